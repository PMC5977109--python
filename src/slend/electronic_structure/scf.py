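"""Unrestricted Hartree-Fock reference determinants.

The SLEND electronic state is parametrized around a reference single
determinant whose molecular spin-orbitals come from a regular SCF UHF
procedure at the initial geometry.  This module provides that SCF
(DIIS-accelerated), Mulliken population analysis, and the fragment
superposition guess used to prepare collision initial states (all
electrons on the target, none on the bare-proton projectile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chem_system.system import MolecularSystem, combine
from .basis import BasisSet, build_basis
from .integrals import IntegralSet, compute_integrals


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, d_energy=None, d_density=None):
        super().__init__(msg)
        self.d_energy = d_energy
        self.d_density = d_density


@dataclass
class ReferenceDeterminant:
    """UHF reference: per-spin MO coefficients over the AO basis.

    Columns of ``C[s]`` are S-orthonormal molecular orbitals, the first
    ``n_occ[s]`` occupied.  The Thouless coefficients z mix the remaining
    (virtual) columns into the occupied ones.
    """

    basis: BasisSet
    C: tuple[np.ndarray, np.ndarray]
    n_occ: tuple[int, int]
    energies: tuple[np.ndarray, np.ndarray]
    energy: float
    converged: bool = True
    history: list = field(default_factory=list)

    def C_occ(self, s: int) -> np.ndarray:
        return self.C[s][:, : self.n_occ[s]]

    def C_virt(self, s: int) -> np.ndarray:
        return self.C[s][:, self.n_occ[s]:]

    def density(self, s: int) -> np.ndarray:
        co = self.C_occ(s)
        return co @ co.conj().T

    @property
    def n_electrons(self) -> int:
        return sum(self.n_occ)

    def spin_flipped(self) -> "ReferenceDeterminant":
        return ReferenceDeterminant(
            self.basis,
            (self.C[1], self.C[0]),
            (self.n_occ[1], self.n_occ[0]),
            (self.energies[1], self.energies[0]),
            self.energy,
            self.converged,
            list(self.history),
        )


def mulliken_charges(
    densities, S: np.ndarray, ao_atom: np.ndarray, atomic_numbers
) -> np.ndarray:
    """Mulliken partial charges q_A = Z_A - sum_{mu in A} (D S)_mumu.

    ``densities`` is an iterable of per-spin AO density matrices; the
    populations of all spins are summed.  The charges sum to the total
    molecular charge by the trace identity tr(D S) = N_sigma.
    """
    ao_atom = np.asarray(ao_atom)
    q = np.array(atomic_numbers, dtype=float)
    for D in densities:
        if D.shape[0] != S.shape[0]:
            raise ValueError("density/overlap dimension mismatch")
        pop = np.real(np.einsum("mn,nm->m", D, S))
        for mu, a in enumerate(ao_atom):
            q[a] -= pop[mu]
    return q


def _build_g(eri: np.ndarray, d_tot: np.ndarray, d_spin: np.ndarray
             ) -> np.ndarray:
    """Coulomb-minus-exchange contraction for one spin channel."""
    j = np.einsum("mnls,ls->mn", eri, d_tot, optimize=True)
    k = np.einsum("mlns,ls->mn", eri, d_spin, optimize=True)
    return j - k


class _DIIS:
    def __init__(self, max_vec: int = 8):
        self.errs: list[np.ndarray] = []
        self.focks: list[tuple[np.ndarray, np.ndarray]] = []
        self.max_vec = max_vec

    def push(self, focks, err):
        self.errs.append(err)
        self.focks.append(focks)
        if len(self.errs) > self.max_vec:
            self.errs.pop(0)
            self.focks.pop(0)

    def extrapolate(self):
        n = len(self.errs)
        if n < 2:
            return self.focks[-1]
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = np.dot(self.errs[i], self.errs[j])
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            w = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return self.focks[-1]
        fa = sum(wi * f[0] for wi, f in zip(w, self.focks))
        fb = sum(wi * f[1] for wi, f in zip(w, self.focks))
        return fa, fb


def run_uhf(
    system: MolecularSystem,
    basis: BasisSet | str,
    max_iter: int = 150,
    conv_e: float = 1e-10,
    conv_d: float = 1e-8,
    integrals: IntegralSet | None = None,
    initial: ReferenceDeterminant | None = None,
) -> ReferenceDeterminant:
    """Converge a spin-unrestricted Hartree-Fock determinant.

    Convergence requires both |dE| < conv_e and an RMS density change
    < conv_d.  The initial guess diagonalizes the core Hamiltonian unless
    an ``initial`` determinant (e.g. from :func:`fragment_guess`) is
    given.  Zero-electron systems return an empty determinant whose total
    energy is the bare nuclear repulsion.
    """
    if isinstance(basis, str):
        basis = build_basis(system, basis)
    ints = integrals or compute_integrals(basis, mode="static")
    S, h, eri, vnn = ints.S, ints.hcore, ints.eri, ints.vnn
    K = basis.K
    na, nb = system.n_alpha, system.n_beta
    if K < na:
        raise ValueError(f"basis too small: K={K} < N_alpha={na}")

    # orthogonalizer
    w, U = np.linalg.eigh(S)
    X = U @ np.diag(w**-0.5) @ U.T

    if na + nb == 0:
        C = X.copy()
        e = np.full(K, np.nan)
        return ReferenceDeterminant(
            basis, (C, C.copy()), (0, 0), (e, e.copy()), vnn, True, [vnn]
        )

    def diag(F):
        Fp = X.T @ F @ X
        e, Cp = np.linalg.eigh(0.5 * (Fp + Fp.T))
        return e, X @ Cp

    if initial is not None:
        Ca, Cb = initial.C[0].copy(), initial.C[1].copy()
        ea = eb = np.zeros(K)
    else:
        ea, Ca = diag(h)
        eb, Cb = ea.copy(), Ca.copy()

    def dens(C, n):
        return C[:, :n] @ C[:, :n].T if n else np.zeros((K, K))

    Da, Db = dens(Ca, na), dens(Cb, nb)
    diis = _DIIS()
    e_old = None
    history: list[float] = []
    for it in range(max_iter):
        Dt = Da + Db
        Fa = h + _build_g(eri, Dt, Da)
        Fb = h + _build_g(eri, Dt, Db)
        energy = 0.5 * (
            np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))
        ) + vnn
        history.append(float(energy))
        erra = X.T @ (Fa @ Da @ S - S @ Da @ Fa) @ X
        errb = X.T @ (Fb @ Db @ S - S @ Db @ Fb) @ X
        err = np.concatenate([erra.ravel(), errb.ravel()])
        diis.push((Fa, Fb), err)
        Fa, Fb = diis.extrapolate()
        ea, Ca = diag(Fa)
        eb, Cb = diag(Fb)
        Da_new, Db_new = dens(Ca, na), dens(Cb, nb)
        d_dens = max(
            float(np.sqrt(np.mean((Da_new - Da) ** 2))),
            float(np.sqrt(np.mean((Db_new - Db) ** 2))),
        )
        d_e = abs(energy - e_old) if e_old is not None else np.inf
        Da, Db = Da_new, Db_new
        e_old = energy
        if d_e < conv_e and d_dens < conv_d:
            Dt = Da + Db
            Fa = h + _build_g(eri, Dt, Da)
            Fb = h + _build_g(eri, Dt, Db)
            energy = 0.5 * (
                np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))
            ) + vnn
            ea, Ca = diag(Fa)
            eb, Cb = diag(Fb)
            return ReferenceDeterminant(
                basis, (Ca, Cb), (na, nb), (ea, eb), float(energy),
                True, history,
            )
    raise SCFConvergenceError(
        f"UHF did not converge in {max_iter} iterations "
        f"(|dE|={d_e:.2e}, d_dens={d_dens:.2e})",
        d_energy=d_e,
        d_density=d_dens,
    )


def fragment_guess(
    fragments: list[tuple[MolecularSystem, ReferenceDeterminant]],
    basis_name: str | None = None,
) -> ReferenceDeterminant:
    """Assemble a supersystem reference from fragment determinants.

    Fragment geometries must already sit in the common supersystem frame
    and the fragment basis sets concatenate (atom-major) to the
    supersystem basis.  Occupied orbitals are the union of the fragment
    occupied orbitals, symmetrically (Lowdin) orthonormalized under the
    supersystem overlap; virtuals are rebuilt by projecting the occupied
    space out of the orthogonalized AO space.
    """
    if not fragments:
        raise ValueError("no fragments")
    names = {det.basis.name for _, det in fragments}
    if basis_name is None:
        if len(names) > 1:
            raise ValueError(f"fragments use different bases: {names}")
        basis_name = names.pop()
    supersystem = combine([s for s, _ in fragments])
    # total spin bookkeeping; relabel spins so alpha is the majority
    n_a = sum(det.n_occ[0] for _, det in fragments)
    n_b = sum(det.n_occ[1] for _, det in fragments)
    flip = n_a < n_b
    if flip:
        n_a, n_b = n_b, n_a
    supersystem = MolecularSystem(
        supersystem.atoms,
        supersystem.charge,
        abs(n_a - n_b) + 1,
        name="+".join(s.name for s, _ in fragments),
    )
    basis = build_basis(supersystem, basis_name)
    K = basis.K
    ints = compute_integrals(basis, mode="static")
    S = ints.S

    C_occ = [np.zeros((K, n_a)), np.zeros((K, n_b))]
    col = [0, 0]
    row = 0
    for sys_f, det in fragments:
        kf = det.basis.K
        for s in range(2):
            sf = 1 - s if flip else s
            n = det.n_occ[sf]
            if n:
                C_occ[s][row: row + kf, col[s]: col[s] + n] = det.C_occ(sf)
                col[s] += n
        row += kf
    if row != K:
        raise ValueError("fragment bases do not concatenate to supersystem")

    w, U = np.linalg.eigh(S)
    X = U @ np.diag(w**-0.5) @ U.T

    C_full = []
    energies = []
    for s, n in zip(range(2), (n_a, n_b)):
        co = C_occ[s]
        if n:
            m = co.T @ S @ co
            ev = np.linalg.eigvalsh(m)
            if ev[0] < 1e-8:
                raise np.linalg.LinAlgError(
                    "fragment occupied spaces are (near-)linearly dependent"
                    f" (smallest metric eigenvalue {ev[0]:.3e})"
                )
            ew, eu = np.linalg.eigh(m)
            co = co @ eu @ np.diag(ew**-0.5) @ eu.T
        # virtuals: project occupied out of the orthogonalized AO space
        Y = X - (co @ (co.T @ S @ X) if n else 0.0)
        G = Y.T @ S @ Y
        gw, gu = np.linalg.eigh(G)
        keep = gw > 1e-8
        nv = K - n
        idx = np.argsort(gw)[::-1][:nv]
        V = Y @ gu[:, idx] @ np.diag(gw[idx] ** -0.5)
        C = np.hstack([co, V]) if n else V
        C_full.append(C)
        energies.append(np.full(K, np.nan))

    # energy and orbital energies from the assembled density
    Da = C_full[0][:, :n_a] @ C_full[0][:, :n_a].T if n_a else np.zeros((K, K))
    Db = C_full[1][:, :n_b] @ C_full[1][:, :n_b].T if n_b else np.zeros((K, K))
    Dt = Da + Db
    h = ints.hcore
    Fa = h + _build_g(ints.eri, Dt, Da)
    Fb = h + _build_g(ints.eri, Dt, Db)
    energy = 0.5 * (np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))) + ints.vnn
    energies[0] = np.real(np.diag(C_full[0].T @ Fa @ C_full[0]))
    energies[1] = np.real(np.diag(C_full[1].T @ Fb @ C_full[1]))

    return ReferenceDeterminant(
        basis,
        (C_full[0], C_full[1]),
        (n_a, n_b),
        (energies[0], energies[1]),
        float(energy),
        True,
        [float(energy)],
    )
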