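"""State containers for the SLEND dynamics.

The dynamical variables are classical nuclear positions/momenta (the
zero-width limit of frozen nuclear Gaussians) and the complex Thouless
coefficients z that mix reference virtual orbitals into the occupied
ones, per spin channel.  Everything else (reference orbitals, basis) is
frozen at preparation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..electronic_structure.scf import ReferenceDeterminant


@dataclass
class NuclearConfiguration:
    """Classical nuclei: R, P (Bohr / a.u.), masses and charges.

    The widths of the underlying Gaussian wave packets are eliminated by
    the zero-width limit and are deliberately not stored.
    """

    positions: np.ndarray  # (natom, 3)
    momenta: np.ndarray  # (natom, 3)
    masses: np.ndarray  # (natom,)
    charges: np.ndarray  # (natom,)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.momenta = np.asarray(self.momenta, float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, float).ravel()
        self.charges = np.asarray(self.charges, float).ravel()
        n = len(self.masses)
        if self.positions.shape != (n, 3) or self.momenta.shape != (n, 3):
            raise ValueError("inconsistent nuclear array lengths")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    def velocities(self) -> np.ndarray:
        return self.momenta / self.masses[:, None]

    def kinetic_energy(self) -> float:
        return float(
            0.5 * np.sum(self.momenta**2 / self.masses[:, None])
        )

    def copy(self) -> "NuclearConfiguration":
        return NuclearConfiguration(
            self.positions.copy(),
            self.momenta.copy(),
            self.masses.copy(),
            self.charges.copy(),
        )


def nuclear_from_system(system, momenta=None) -> NuclearConfiguration:
    momenta = (
        np.zeros((system.n_atoms, 3)) if momenta is None else momenta
    )
    return NuclearConfiguration(
        system.positions, momenta, system.masses, system.charges
    )


@dataclass
class ThoulessState:
    """A SLEND phase-space point: (z, R, P) over a fixed reference."""

    reference: ReferenceDeterminant
    nuclear: NuclearConfiguration
    z: list  # per spin: complex (K - N_s, N_s)
    time: float = 0.0
    etf_mode: str = "static"

    def __post_init__(self):
        K = self.reference.basis.K
        zs = []
        for s in range(2):
            n = self.reference.n_occ[s]
            arr = np.asarray(self.z[s], dtype=complex).reshape(K - n, n)
            if not np.all(np.isfinite(arr.view(float))):
                raise ValueError("non-finite Thouless coefficients")
            zs.append(arr)
        self.z = zs

    @property
    def basis(self):
        return self.reference.basis

    @property
    def n_z(self) -> tuple[int, int]:
        return tuple(z.size for z in self.z)

    def z_norm(self) -> float:
        return float(
            np.sqrt(sum(np.sum(np.abs(z) ** 2) for z in self.z))
        )

    def dso_coefficients(self, s: int) -> np.ndarray:
        """AO coefficients of the dynamical spin-orbitals
        chi_h = phi_h + sum_p z_ph phi_p for spin s: (K, N_s)."""
        ref = self.reference
        return ref.C_occ(s).astype(complex) + ref.C_virt(s).astype(
            complex
        ) @ self.z[s]

    def copy(self) -> "ThoulessState":
        return ThoulessState(
            self.reference,
            self.nuclear.copy(),
            [z.copy() for z in self.z],
            self.time,
            self.etf_mode,
        )

    # ---- flat real parameter vector [Re z, Im z, R, P] ----
    def pack(self) -> np.ndarray:
        re = np.concatenate(
            [self.z[0].ravel().real, self.z[1].ravel().real]
        )
        im = np.concatenate(
            [self.z[0].ravel().imag, self.z[1].ravel().imag]
        )
        return np.concatenate(
            [re, im, self.nuclear.positions.ravel(),
             self.nuclear.momenta.ravel()]
        )

    def unpack(self, y: np.ndarray, time: float | None = None
               ) -> "ThoulessState":
        nz = sum(self.n_z)
        n0, n1 = self.n_z
        re, im = y[:nz], y[nz: 2 * nz]
        z0 = (re[:n0] + 1j * im[:n0]).reshape(self.z[0].shape)
        z1 = (re[n0:] + 1j * im[n0:]).reshape(self.z[1].shape)
        natom = self.nuclear.n_atoms
        R = y[2 * nz: 2 * nz + 3 * natom].reshape(natom, 3)
        P = y[2 * nz + 3 * natom:].reshape(natom, 3)
        nuc = NuclearConfiguration(
            R.copy(), P.copy(), self.nuclear.masses.copy(),
            self.nuclear.charges.copy(),
        )
        return ThoulessState(
            self.reference, nuc, [z0, z1],
            self.time if time is None else time, self.etf_mode,
        )

    def time_reversed(self) -> "ThoulessState":
        """Momentum reversal + complex conjugation of z (time reversal)."""
        nuc = self.nuclear.copy()
        nuc.momenta = -nuc.momenta
        return ThoulessState(
            self.reference, nuc, [np.conj(z) for z in self.z],
            self.time, self.etf_mode,
        )


@dataclass
class CouplingMatrices:
    """The generalized non-adiabatic coupling blocks.

    ``C`` is the Hermitian z-z metric (flattened (p,h) x (q,g)); ``C_R``
    and ``C_P`` couple z to nuclear coordinates; ``C_XY`` is the real
    antisymmetric nuclear-nuclear block -2 Im d2 lnS / dX' dY over the
    stacked (R, P) coordinates.
    """

    C: np.ndarray
    C_R: np.ndarray
    C_P: np.ndarray
    C_XY: np.ndarray


@dataclass
class DerivativeBundle:
    """Gradients of the total energy in the conjugate-z convention."""

    dE_dz_conj: list  # per spin, complex (V_s, N_s)
    dE_dR: np.ndarray  # (3*natom,)
    dE_dP: np.ndarray  # (3*natom,)


@dataclass
class Frame:
    time: float
    positions: np.ndarray
    momenta: np.ndarray
    z: list
    energy: float
    mulliken: np.ndarray
    z_norm: float
    step_size: float
    rcond: float
    h_next: float = float("nan")  # integrator trial step (restart seed)


@dataclass
class Trajectory:
    """Time-ordered SLEND frames with per-frame diagnostics."""

    reference: ReferenceDeterminant
    etf_mode: str
    frames: list = field(default_factory=list)
    end_reason: str = ""
    meta: dict = field(default_factory=dict)

    def add(self, frame: Frame) -> None:
        if self.frames and frame.time <= self.frames[-1].time:
            raise ValueError("trajectory times must strictly increase")
        self.frames.append(frame)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])

    @property
    def mulliken(self) -> np.ndarray:
        return np.array([f.mulliken for f in self.frames])

    def final_state(self) -> ThoulessState:
        f = self.frames[-1]
        nuc = NuclearConfiguration(
            f.positions.copy(),
            f.momenta.copy(),
            self.meta["masses"].copy(),
            self.meta["charges"].copy(),
        )
        return ThoulessState(
            self.reference, nuc, [z.copy() for z in f.z], f.time,
            self.etf_mode,
        )
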