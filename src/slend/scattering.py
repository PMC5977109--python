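"""Initial-state preparation and scenario driving.

Three scenario families: proton-target collisions (the projectile is a
bare H+ carrying its own travelling basis functions, all electrons
prepared on the target via the fragment-superposition guess), electron
attachment to a chosen virtual orbital of a neutral host (the
shape-resonance surrogate: the dynamics starts just after capture), and
plain propagation of a prepared state until a stopping rule fires.

Beam-frame convention (recorded in every trajectory's metadata): the
beam travels along +x, the impact parameter is applied along +y, and the
aim point sits at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem_system.system import Atom, MolecularSystem
from .chem_system.units import PROTON_MASS_AU, projectile_speed
from .electronic_structure.basis import build_basis
from .electronic_structure.integrals import compute_integrals
from .electronic_structure.scf import (
    ReferenceDeterminant,
    fragment_guess,
    run_uhf,
)
from .thouless_dynamics.state import (
    NuclearConfiguration,
    ThoulessState,
    Trajectory,
)
from .thouless_dynamics.propagate import PropagationControls, propagate

#: collision energies at or above this (keV) default to the travelling
#: basis; below it the static basis is the default.
ETF_AUTO_THRESHOLD_KEV = 10.0
#: maximum tolerated projectile-target basis overlap at preparation
FRAGMENT_OVERLAP_TOL = 1e-8


@dataclass
class CollisionSpec:
    """A single proton-target collision setup."""

    target: MolecularSystem
    energy_kev: float
    impact_parameter: float  # Bohr, along +y
    basis: str = "sto-3g"
    separation: float = 30.0  # Bohr, along -x from the aim point
    orientation: np.ndarray | None = None  # 3x3 rotation of the target
    aim: str | int = "com"  # 'com' or target atom index
    etf_mode: str = "auto"  # 'auto' | 'static' | 'travelling'
    projectile_mass: float = PROTON_MASS_AU

    def __post_init__(self):
        if self.impact_parameter < 0:
            raise ValueError("impact parameter must be >= 0")
        if self.energy_kev < 0:
            raise ValueError("collision energy must be >= 0")

    def resolved_mode(self) -> str:
        if self.etf_mode != "auto":
            return self.etf_mode
        return (
            "travelling"
            if self.energy_kev >= ETF_AUTO_THRESHOLD_KEV
            else "static"
        )


@dataclass
class AttachmentSpec:
    """Electron attachment to a virtual orbital of a neutral host.

    ``virtual_offset`` counts from the LUMO of the chosen spin channel
    (0 = LUMO, 2 = LUMO+2, ...).  The simulation starts just after
    capture: the extra electron occupies the selected canonical virtual
    orbital and the nuclei are at rest.
    """

    host: MolecularSystem
    virtual_offset: int = 0
    spin: str = "alpha"
    basis: str = "sto-3g"

    def __post_init__(self):
        if self.spin not in ("alpha", "beta"):
            raise ValueError("spin must be 'alpha' or 'beta'")
        if self.virtual_offset < 0:
            raise ValueError("virtual offset must be >= 0")


@dataclass
class StoppingRule:
    """Trajectory termination conditions; at least one must be active."""

    max_time: float | None = None
    projectile_separation: float | None = None  # Bohr from rest-of-system com
    fragment_separation: float | None = None  # Bohr, min inter-fragment gap

    def __post_init__(self):
        if (
            self.max_time is None
            and self.projectile_separation is None
            and self.fragment_separation is None
        ):
            raise ValueError("at least one stopping rule must be active")


def sample_orientations(count: int, seed: int) -> list[np.ndarray]:
    """Uniform random rotation matrices via unit-quaternion sampling."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        out.append(
            np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w),
                     2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z),
                     2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w),
                     1 - 2 * (x * x + y * y)],
                ]
            )
        )
    return out


def _place_target(spec: CollisionSpec) -> MolecularSystem:
    """Rotate the target about its center of mass, put the aim point at
    the origin."""
    target = spec.target
    pos = target.positions
    com = np.average(pos, axis=0, weights=target.masses)
    pos = pos - com
    if spec.orientation is not None:
        R = np.asarray(spec.orientation, float).reshape(3, 3)
        pos = pos @ R.T
    if spec.aim == "com":
        shift = np.zeros(3)
    else:
        shift = pos[int(spec.aim)].copy()
    return target.with_positions(pos - shift)


def prepare_collision(spec: CollisionSpec) -> ThoulessState:
    """Build the initial SLEND state for a proton-target collision.

    Target electrons are prepared on the target fragment (fragment
    superposition, z = 0); the bare-proton projectile starts at
    (-separation, +b, 0) with momentum m*v along +x.
    """
    target = _place_target(spec)
    v = projectile_speed(spec.energy_kev, spec.projectile_mass)
    proj_pos = np.array(
        [-spec.separation, spec.impact_parameter, 0.0]
    )
    projectile = MolecularSystem(
        [Atom("H", proj_pos, mass=spec.projectile_mass)], 1, 1,
        name="H+ projectile",
    )
    det_t = run_uhf(target, spec.basis)
    det_p = run_uhf(projectile, spec.basis)
    ref = fragment_guess([(target, det_t), (projectile, det_p)])

    # preparation sanity: projectile and target bases must not overlap
    ints = compute_integrals(ref.basis, mode="static", need_eri=False)
    kt = det_t.basis.K
    cross = float(np.abs(ints.S[:kt, kt:]).max())
    if cross > FRAGMENT_OVERLAP_TOL:
        raise ValueError(
            f"initial separation too small: fragment overlap {cross:.2e} "
            f"> {FRAGMENT_OVERLAP_TOL:g}"
        )

    momenta = np.zeros((ref.basis.system.n_atoms, 3))
    momenta[-1, 0] = spec.projectile_mass * v
    nuc = NuclearConfiguration(
        ref.basis.system.positions,
        momenta,
        ref.basis.system.masses,
        ref.basis.system.charges,
    )
    K = ref.basis.K
    z = [
        np.zeros((K - ref.n_occ[s], ref.n_occ[s]), dtype=complex)
        for s in range(2)
    ]
    return ThoulessState(ref, nuc, z, 0.0, spec.resolved_mode())


def prepare_attachment(spec: AttachmentSpec) -> ThoulessState:
    """Insert one electron into a canonical virtual orbital of the host.

    Returns a state with electron count = host count + 1 and total
    charge = host charge - 1; no orbital relaxation is applied before
    propagation (the inserted orbital plays the metastable
    shape-resonant role).
    """
    host = spec.host
    det = run_uhf(host, spec.basis)
    s = 0 if spec.spin == "alpha" else 1
    K = det.basis.K
    n = det.n_occ[s]
    if n + spec.virtual_offset >= K:
        raise IndexError(
            f"virtual selector LUMO+{spec.virtual_offset} out of range "
            f"(only {K - n} virtuals in spin channel {spec.spin})"
        )
    sel = n + spec.virtual_offset

    anion = MolecularSystem(
        list(host.atoms),
        host.charge - 1,
        _anion_multiplicity(det, s),
        name=(host.name or "host") + "_anion",
    )
    basis = build_basis(anion, spec.basis)

    order = (
        list(range(n)) + [sel]
        + [i for i in range(n, K) if i != sel]
    )
    C_s = det.C[s][:, order]
    e_s = det.energies[s][order]
    n_occ = [det.n_occ[0], det.n_occ[1]]
    n_occ[s] += 1
    C = [det.C[0], det.C[1]]
    C[s] = C_s
    energies = [det.energies[0], det.energies[1]]
    energies[s] = e_s
    ref = ReferenceDeterminant(
        basis,
        (C[0], C[1]),
        (n_occ[0], n_occ[1]),
        (energies[0], energies[1]),
        det.energy + det.energies[s][sel],
        det.converged,
        [],
    )
    if ref.n_occ[0] < ref.n_occ[1]:
        ref = ref.spin_flipped()
    nuc = NuclearConfiguration(
        anion.positions,
        np.zeros((anion.n_atoms, 3)),
        anion.masses,
        anion.charges,
    )
    z = [
        np.zeros((K - ref.n_occ[t], ref.n_occ[t]), dtype=complex)
        for t in range(2)
    ]
    return ThoulessState(ref, nuc, z, 0.0, "static")


def _anion_multiplicity(det: ReferenceDeterminant, s: int) -> int:
    n_occ = [det.n_occ[0], det.n_occ[1]]
    n_occ[s] += 1
    return abs(n_occ[0] - n_occ[1]) + 1


def _stop_condition(stopping: StoppingRule, projectile_index: int | None):
    from .analysis import identify_fragments

    def cond(state: ThoulessState) -> str | None:
        nuc = state.nuclear
        if (
            stopping.projectile_separation is not None
            and projectile_index is not None
        ):
            pos = nuc.positions
            rest = np.delete(pos, projectile_index, axis=0)
            w = np.delete(nuc.masses, projectile_index)
            com = np.average(rest, axis=0, weights=w)
            if (
                np.linalg.norm(pos[projectile_index] - com)
                > stopping.projectile_separation
            ):
                return "separation"
        if stopping.fragment_separation is not None:
            frags = identify_fragments(
                nuc.positions,
                [int(z) for z in nuc.charges],
            )
            if len(frags.fragments) > 1:
                gap = _min_fragment_gap(nuc.positions, frags.fragments)
                if gap > stopping.fragment_separation:
                    return "fragmentation"
        return None

    return cond


def _min_fragment_gap(positions, fragments) -> float:
    gap = np.inf
    for i in range(len(fragments)):
        for j in range(i + 1, len(fragments)):
            for a in fragments[i]:
                for b in fragments[j]:
                    gap = min(
                        gap,
                        float(
                            np.linalg.norm(positions[a] - positions[b])
                        ),
                    )
    return gap


def run_scenario(
    initial: ThoulessState,
    stopping: StoppingRule,
    controls: PropagationControls | None = None,
    projectile_index: int | None = None,
) -> Trajectory:
    """Propagate until a stopping rule fires.

    The trajectory records which rule ended the run; its last frame is
    the product stage.  ``projectile_index`` (usually the last atom for
    prepared collisions) enables the projectile-separation rule.
    """
    controls = controls or PropagationControls()
    t_end = (
        initial.time + stopping.max_time
        if stopping.max_time is not None
        else initial.time + 1e9
    )
    controls = replace(
        controls, stop_condition=_stop_condition(stopping, projectile_index)
    )
    traj = propagate(initial, t_end, controls)
    traj.meta["beam_frame"] = "beam +x, impact parameter +y, aim at origin"
    traj.meta["etf_mode"] = initial.etf_mode
    traj.meta["projectile_index"] = projectile_index
    traj.frames[-1].__dict__.setdefault("product_stage", True)
    return traj
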