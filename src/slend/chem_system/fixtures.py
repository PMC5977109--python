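"""Built-in molecular fixtures.

The collision and attachment scenarios in this package operate on small,
fully specified prototype systems: one- and two-electron diatomics for
validation, the water monomer, and hydrogen-bonded water clusters
(H2O)_n, n = 2-6, whose electron-transfer cross sections grow with the
cluster surface area.

Coordinate provenance
---------------------
No coordinates are fitted here at run time.  Diatomics use documented
standard bond lengths; the water monomer uses the experimental equilibrium
geometry (r_OH = 0.9572 Angstrom, HOH angle 104.52 deg).  Cluster
geometries are *synthetic idealized* structures constructed by rule from
the monomer: cyclic minima for n = 3-5 (ring of hydrogen-bonded waters,
free hydrogens alternating above/below the ring plane, O-O 2.75 Angstrom),
the near-S4 cyclic tetramer, and stacked-ring prism/cage-like hexamers.
They approximate the named isomer classes (ring, prism, cage, asymmetric)
rather than reproducing any particular published minimum; exact literature
isomer coordinates are deliberately not embedded.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable

import numpy as np

from .system import Atom, MolecularSystem, read_xyz
from .units import BOHR_ANGSTROM

# Experimental equilibrium water monomer (Angstrom / degrees).
_R_OH = 0.9572
_A_HOH = 104.52
# Idealized hydrogen-bond O-O distance used by the cluster builders.
_R_OO = 2.75


def _ang(x: float) -> float:
    return x / BOHR_ANGSTROM


def _diatomic(sym1: str, sym2: str, r_bohr: float, charge: int, mult: int,
              name: str) -> MolecularSystem:
    return MolecularSystem(
        [
            Atom(sym1, np.array([0.0, 0.0, 0.0])),
            Atom(sym2, np.array([0.0, 0.0, r_bohr])),
        ],
        charge=charge,
        multiplicity=mult,
        name=name,
    )


def _h2() -> MolecularSystem:
    # 1.4 Bohr: the documented fixture default, close to the STO-3G
    # equilibrium; validated in the test suite by an SCF bond scan.
    return _diatomic("H", "H", 1.4, 0, 1, "h2")


def _h2_plus() -> MolecularSystem:
    return _diatomic("H", "H", 2.0, 1, 2, "h2_plus")


def _heh_plus() -> MolecularSystem:
    # Classic two-electron benchmark separation of 1.4632 Bohr.
    return _diatomic("He", "H", 1.4632, 1, 1, "heh_plus")


def _water_atoms(origin: np.ndarray, x_axis: np.ndarray, y_axis: np.ndarray
                 ) -> list[Atom]:
    """One water monomer: O at origin, OH bonds in the (x_axis, y_axis)
    plane, bisector along +x_axis.  Axes must be orthonormal."""
    half = math.radians(_A_HOH / 2.0)
    r = _ang(_R_OH)
    atoms = [Atom("O", origin)]
    for sgn in (+1.0, -1.0):
        d = math.cos(half) * x_axis + sgn * math.sin(half) * y_axis
        atoms.append(Atom("H", origin + r * d))
    return atoms


def _h2o() -> MolecularSystem:
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    atoms = _water_atoms(np.zeros(3), ex, ey)
    return MolecularSystem(atoms, 0, 1, name="h2o")


def _oh_minus() -> MolecularSystem:
    return _diatomic("O", "H", _ang(0.964), -1, 1, "oh_minus")


def _h3po4() -> MolecularSystem:
    """Synthetic idealized orthophosphoric acid (C3-like propeller).

    Stand-in host for phosphate-site electron attachment studies when the
    full excised-nucleotide geometry (user-supplied) is not available.
    Idealized bonds: P=O 1.48, P-O(H) 1.57, O-H 0.96 Angstrom; tetrahedral
    angles.  Synthetic geometry, not an optimized minimum.
    """
    atoms = [Atom("P", np.zeros(3))]
    # P=O along +z.
    atoms.append(Atom("O", np.array([0.0, 0.0, _ang(1.48)])))
    theta = math.radians(112.0)  # O=P-O(H) angle
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        d = np.array(
            [math.sin(theta) * math.cos(phi),
             math.sin(theta) * math.sin(phi),
             math.cos(theta)]
        )
        o_pos = _ang(1.57) * d
        atoms.append(Atom("O", o_pos))
        # O-H roughly tangential, tilted away from P.
        tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
        h_dir = 0.55 * d + 0.83 * tangent
        h_dir /= np.linalg.norm(h_dir)
        atoms.append(Atom("H", o_pos + _ang(0.96) * h_dir))
    return MolecularSystem(atoms, 0, 1, name="h3po4")


def _ring_cluster(n: int, name: str, tilt: float = 0.0,
                  asym: float = 0.0) -> MolecularSystem:
    """Cyclic (H2O)_n: each O donates one H to the next O around a ring.

    The donated H points along the O-O hydrogen bond; the free H
    alternates above/below the ring plane (the near-S4 pattern for n=4).
    ``asym`` displaces one monomer radially to produce the "more
    asymmetric" isomer classes.
    """
    r_ring = _ang(_R_OO) / (2.0 * math.sin(math.pi / n))
    r_oh = _ang(_R_OH)
    atoms: list[Atom] = []
    for k in range(n):
        phi = 2.0 * math.pi * k / n
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        o = r_ring * radial
        if asym and k == 0:
            o = o + asym * radial
        phi_next = 2.0 * math.pi * ((k + 1) % n) / n
        o_next = r_ring * np.array(
            [math.cos(phi_next), math.sin(phi_next), 0.0]
        )
        if asym and (k + 1) % n == 0:
            o_next = o_next + asym * np.array(
                [math.cos(phi_next), math.sin(phi_next), 0.0]
            )
        # Donor H along the hydrogen bond towards the next O.
        hb = o_next - o
        hb /= np.linalg.norm(hb)
        h_donor = o + r_oh * hb
        # Free H alternating up/down, tilted off the plane.
        up = (-1.0) ** k
        free = np.array([0.35 * math.cos(phi), 0.35 * math.sin(phi),
                         up * 1.0])
        if tilt:
            free[2] *= 1.0 + tilt
        free /= np.linalg.norm(free)
        h_free = o + r_oh * free
        atoms += [Atom("O", o), Atom("H", h_donor), Atom("H", h_free)]
    return MolecularSystem(atoms, 0, 1, name=name)


def _dimer() -> MolecularSystem:
    """Near-linear hydrogen-bonded water dimer (O-O 2.98 Angstrom)."""
    r_oh = _ang(_R_OH)
    half = math.radians(_A_HOH / 2.0)
    # Donor water: O at origin, donated H along +x towards the acceptor.
    o1 = np.zeros(3)
    h1a = o1 + r_oh * np.array([1.0, 0.0, 0.0])
    h1b = o1 + r_oh * np.array(
        [math.cos(math.radians(_A_HOH)), math.sin(math.radians(_A_HOH)), 0.0]
    )
    # Acceptor water beyond the H bond, bisector tilted out of the O-O axis.
    o2 = np.array([_ang(2.98), 0.0, 0.0])
    ex = np.array([math.cos(math.radians(120.0)), 0.0,
                   math.sin(math.radians(120.0))])
    ez = np.array([-math.sin(math.radians(120.0)), 0.0,
                   math.cos(math.radians(120.0))])
    atoms = [Atom("O", o1), Atom("H", h1a), Atom("H", h1b)]
    half = math.radians(_A_HOH / 2.0)
    for sgn in (+1.0, -1.0):
        d = math.cos(half) * ex + sgn * math.sin(half) * ez
        atoms.append(Atom("H", o2 + r_oh * d))
    atoms.insert(3, Atom("O", o2))
    return MolecularSystem(atoms, 0, 1, name="water_cluster_n2")


def _prism() -> MolecularSystem:
    """Prism-like (H2O)_6: two stacked cyclic trimers (synthetic)."""
    top = _ring_cluster(3, "tmp")
    bottom = _ring_cluster(3, "tmp")
    dz = _ang(2.85)
    atoms: list[Atom] = []
    for a in top.atoms:
        atoms.append(Atom(a.symbol, a.position + np.array([0, 0, dz / 2])))
    rot = math.pi / 3.0  # stagger the lower ring
    c, s = math.cos(rot), math.sin(rot)
    rmat = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    for a in bottom.atoms:
        p = rmat @ a.position
        atoms.append(Atom(a.symbol, p - np.array([0, 0, dz / 2])))
    return MolecularSystem(atoms, 0, 1, name="water_cluster_n6_prism")


def _cage() -> MolecularSystem:
    """Cage-like (H2O)_6: stacked staggered rings, compressed (synthetic)."""
    sys = _prism()
    # Squeeze radially and shear to break the prism symmetry cage-wards.
    atoms = []
    for k, a in enumerate(sys.atoms):
        p = a.position.copy()
        p[0] *= 0.92
        p[1] *= 1.05
        p[0] += 0.25 * math.copysign(1.0, p[2])
        atoms.append(Atom(a.symbol, p))
    return MolecularSystem(atoms, 0, 1, name="water_cluster_n6_cage")


_FIXTURES: dict[str, Callable[[], MolecularSystem]] = {
    "h2": _h2,
    "h2_plus": _h2_plus,
    "heh_plus": _heh_plus,
    "h2o": _h2o,
    "oh_minus": _oh_minus,
    "h3po4": _h3po4,
    "water_cluster_n2": _dimer,
    "water_cluster_n3": lambda: _ring_cluster(3, "water_cluster_n3"),
    "water_cluster_n4_s4": lambda: _ring_cluster(4, "water_cluster_n4_s4"),
    "water_cluster_n4_asym": lambda: _ring_cluster(
        4, "water_cluster_n4_asym", tilt=0.3, asym=0.9),
    "water_cluster_n5": lambda: _ring_cluster(5, "water_cluster_n5"),
    "water_cluster_n5_asym": lambda: _ring_cluster(
        5, "water_cluster_n5_asym", tilt=0.3, asym=0.9),
    "water_cluster_n6_prism": _prism,
    "water_cluster_n6_cage": _cage,
    "water_cluster_n6_asym": lambda: _ring_cluster(
        6, "water_cluster_n6_asym", tilt=0.25, asym=1.1),
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def build_fixture(name: str) -> MolecularSystem:
    """Return a registered fixture, or read a user XYZ file.

    ``name`` is either a registry key (see :func:`list_fixtures`) or a path
    to an XYZ file — the latter is how user-supplied geometries such as the
    excised nucleotide enter the package.  Deterministic: no randomness.
    """
    key = name.lower()
    if key in _FIXTURES:
        return _FIXTURES[key]()
    path = Path(name)
    if path.suffix.lower() == ".xyz" or path.exists():
        if not path.exists():
            raise FileNotFoundError(f"XYZ file {name!r} not found")
        return read_xyz(path)
    raise KeyError(
        f"unknown fixture {name!r}; known fixtures: {', '.join(list_fixtures())}"
    )
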