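"""SLEND equations of motion.

The dynamics follows from the time-dependent variational principle for a
trial state |R,P> |z;R,P>: classical frozen-Gaussian nuclei in the
zero-width limit times a Thouless single determinant over travelling
basis functions.  Writing the real parameter vector
y = (Re z, Im z, R, P), the first-order Lagrangian

    L = sum_A P_A . R_A'  - Im[ <psi| d/dt |psi> ] / <psi|psi>  - E(y)

yields a Pfaffian (antisymmetric) linear system

    Omega(y) y' = dE/dy,     Omega = K + J,

where J is the canonical nuclear symplectic block and
K_ij = -2 Im d^2 ln S / dX'_i dX''_j evaluated at the diagonal
(bra parameters primed), i.e. exactly the generalized non-adiabatic
coupling blocks C, C_X, C_XY over real coordinates.  The conventional
four-block (z, z*, R, P) matrix form of the dynamical equations is a
regrouping of this same system; deriving Omega directly from the
Euler-Lagrange route keeps every sign and factor tied to one
derivation, and the antisymmetry of K is verified numerically at every
assembly.

All ln S derivatives reduce to dense linear algebra over the per-spin
occupied metric M = D^dag S D with D = C_occ + C_virt z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lapack, lu_factor, lu_solve

from ..electronic_structure import engine
from ..electronic_structure.integrals import (
    DerivativeIntegrals,
    compute_derivative_integrals,
)
from ..electronic_structure.scf import mulliken_charges
from .state import (
    CouplingMatrices,
    DerivativeBundle,
    NuclearConfiguration,
    ThoulessState,
)


class SingularMetricError(RuntimeError):
    """The Thouless metric or the assembled Pfaffian system is singular.

    Carries the reciprocal condition estimate; such singularities are
    physical (the state has left the coordinate patch of the current
    reference) and must halt propagation rather than be regularized."""

    def __init__(self, msg: str, rcond: float):
        super().__init__(f"{msg} (rcond={rcond:.3e})")
        self.rcond = rcond


_RCOND_MIN = 1e-12
_ANTISYM_TOL = 1e-7


def thouless_overlap(bra: ThoulessState, ket: ThoulessState) -> complex:
    """S = <z', R', P' | z, R, P> between two states over one reference.

    Computed per spin as det(D'^dag S_ao D), product over spins; the AO
    overlap S_ao connects the basis at the bra and ket nuclear
    configurations (with momentum phases in travelling mode).
    """
    if bra.reference is not ket.reference:
        raise ValueError("bra and ket must share a reference determinant")
    basis = ket.basis
    vb = bra.nuclear.velocities() if bra.etf_mode == "travelling" else None
    vk = ket.nuclear.velocities() if ket.etf_mode == "travelling" else None
    bfns = engine.basis_terms(basis, bra.nuclear.positions, vb)
    kfns = engine.basis_terms(basis, ket.nuclear.positions, vk)
    s_ao = engine.overlap_matrix(bfns, kfns)
    out = 1.0 + 0.0j
    for s in range(2):
        n = bra.reference.n_occ[s]
        if n == 0:
            continue
        Db = bra.dso_coefficients(s)
        Dk = ket.dso_coefficients(s)
        m = Db.conj().T @ s_ao @ Dk
        det = np.linalg.det(m)
        out *= det
    return complex(out)


@dataclass
class _SpinBlocks:
    D: np.ndarray
    Vt: np.ndarray
    F: np.ndarray  # inv(M)
    rho: np.ndarray
    n: int


class EOMWorkspace:
    """All quantities needed at one phase-space point.

    Evaluates the AO integral derivative bundle once, then exposes the
    energy, its gradients, the coupling matrices and the assembled
    Pfaffian system.
    """

    def __init__(self, state: ThoulessState,
                 ders: DerivativeIntegrals | None = None):
        self.state = state
        ref = state.reference
        self.K = ref.basis.K
        self.natom = state.nuclear.n_atoms
        nuc = state.nuclear
        self.need_eri = ref.n_electrons > 1
        mode = state.etf_mode
        if ders is None:
            ders = compute_derivative_integrals(
                ref.basis,
                nuc.positions,
                velocities=nuc.velocities() if mode == "travelling" else None,
                mode=mode,
                need_eri=self.need_eri,
            )
        self.d = ders
        self.S = ders.values.S.astype(complex)
        self.h = ders.values.hcore.astype(complex)
        self.eri = ders.values.eri
        self.spins: list[_SpinBlocks | None] = []
        for s in range(2):
            n = ref.n_occ[s]
            if n == 0:
                self.spins.append(None)
                continue
            D = state.dso_coefficients(s)
            Vt = ref.C_virt(s).astype(complex)
            M = D.conj().T @ self.S @ D
            try:
                F = np.linalg.inv(M)
            except np.linalg.LinAlgError:
                raise SingularMetricError(
                    "singular DSO overlap (state collapse)", 0.0
                ) from None
            cond = np.linalg.cond(M)
            if cond > 1.0 / _RCOND_MIN:
                raise SingularMetricError(
                    "ill-conditioned DSO overlap", 1.0 / cond
                )
            rho = D @ F @ D.conj().T
            self.spins.append(_SpinBlocks(D, Vt, F, rho, n))
        self.rho_t = sum(
            (sb.rho for sb in self.spins if sb is not None),
            np.zeros((self.K, self.K), dtype=complex),
        )
        self._focks: list[np.ndarray | None] | None = None

    # ---- energies -------------------------------------------------
    def electronic_energy(self) -> float:
        e1 = sum(
            np.trace(self.h @ sb.rho) for sb in self.spins if sb is not None
        )
        e2 = 0.0
        if self.need_eri and self.eri is not None:
            rt = self.rho_t
            e2 = 0.5 * np.einsum(
                "mnls,nm,sl->", self.eri, rt, rt, optimize=True
            )
            for sb in self.spins:
                if sb is None:
                    continue
                e2 -= 0.5 * np.einsum(
                    "mnls,sm,nl->", self.eri, sb.rho, sb.rho, optimize=True
                )
        return float(np.real(e1 + e2))

    def total_energy(self) -> float:
        return (
            self.state.nuclear.kinetic_energy()
            + self.electronic_energy()
            + self.d.values.vnn
        )

    def fock_like(self, s: int) -> np.ndarray:
        """h + dE2/drho_s — the AO effective one-body operator."""
        if self._focks is None:
            self._focks = [None, None]
        if self._focks[s] is None:
            G = self.h.copy()
            if self.need_eri and self.eri is not None:
                sb = self.spins[s]
                G = G + np.einsum(
                    "mnls,sl->mn", self.eri, self.rho_t, optimize=True
                )
                if sb is not None:
                    G = G - np.einsum(
                        "mlsn,ls->mn", self.eri, sb.rho, optimize=True
                    )
            self._focks[s] = G
        return self._focks[s]

    # ---- gradients ------------------------------------------------
    def dE_dz_conj(self) -> list:
        out = []
        for s in range(2):
            sb = self.spins[s]
            if sb is None or sb.Vt.shape[1] == 0:
                out.append(
                    np.zeros(
                        (self.K - (sb.n if sb else 0), sb.n if sb else 0),
                        dtype=complex,
                    )
                )
                continue
            fao = self.fock_like(s)
            proj = np.eye(self.K) - self.S @ sb.rho
            out.append(sb.Vt.conj().T @ proj @ fao @ sb.D @ sb.F)
        return out

    def _nuclear_grad(self, dh, dS_full, deri, dvnn, kinetic_grad
                      ) -> np.ndarray:
        nc = dh.shape[0]
        g = np.zeros(nc)
        rt = self.rho_t
        for c in range(nc):
            acc = 0.0 + 0.0j
            for s in range(2):
                sb = self.spins[s]
                if sb is None:
                    continue
                acc += np.trace(dh[c] @ sb.rho)
                fao = self.fock_like(s)
                acc -= np.trace(fao @ sb.rho @ dS_full[c] @ sb.rho)
            if deri is not None:
                acc += 0.5 * np.einsum(
                    "mnls,nm,sl->", deri[c], rt, rt, optimize=True
                )
                for s in range(2):
                    sb = self.spins[s]
                    if sb is None:
                        continue
                    acc -= 0.5 * np.einsum(
                        "mnls,sm,nl->", deri[c], sb.rho, sb.rho,
                        optimize=True,
                    )
            g[c] = np.real(acc) + dvnn[c] + kinetic_grad[c]
        return g

    def dE_dR(self) -> np.ndarray:
        d = self.d
        nc = 3 * self.natom
        dS_full = [d.dSk_R[c] + d.dSk_R[c].conj().T for c in range(nc)]
        return self._nuclear_grad(
            d.dh_R, dS_full, d.deri_R if self.need_eri else None,
            d.dvnn, np.zeros(nc),
        )

    def dE_dP(self) -> np.ndarray:
        nuc = self.state.nuclear
        kin = (nuc.momenta / nuc.masses[:, None]).ravel()
        if self.state.etf_mode == "static":
            return kin
        d = self.d
        nc = 3 * self.natom
        dS_full = [d.dSk_P[c] + d.dSk_P[c].conj().T for c in range(nc)]
        return self._nuclear_grad(
            d.dh_P, dS_full, d.deri_P if self.need_eri else None,
            np.zeros(nc), kin,
        )

    def gradients(self) -> DerivativeBundle:
        return DerivativeBundle(self.dE_dz_conj(), self.dE_dR(), self.dE_dP())

    # ---- lnS second derivatives (coupling blocks) ------------------
    def _g1(self, s: int) -> np.ndarray:
        """d2 lnS / dz'*_ph dz_qg as (p,h) x (q,g) matrix."""
        sb = self.spins[s]
        nv = self.K - (sb.n if sb else 0)
        if sb is None or nv == 0:
            return np.zeros((0, 0), dtype=complex)
        SV = self.S @ sb.Vt
        SD = self.S @ sb.D
        A = sb.Vt.conj().T @ SV - (sb.Vt.conj().T @ SD) @ sb.F @ (
            sb.D.conj().T @ SV
        )
        # C[(p,h),(q,g)] = A[p,q] F[g,h]
        return np.einsum("pq,gh->phqg", A, sb.F).reshape(
            nv * sb.n, nv * sb.n
        )

    def _g2(self, s: int, dK: np.ndarray) -> np.ndarray:
        """d2 lnS / dz'*_ph dX''_c for one coordinate's AO matrix dK."""
        sb = self.spins[s]
        proj = np.eye(self.K) - self.S @ sb.rho
        return (sb.Vt.conj().T @ proj @ dK @ sb.D @ sb.F).reshape(-1)

    def _g2b(self, s: int, dKb: np.ndarray) -> np.ndarray:
        """d2 lnS / dX'_c dz''_qg, flattened over (q,g)."""
        sb = self.spins[s]
        proj = np.eye(self.K) - sb.rho @ self.S
        m = sb.F @ sb.D.conj().T @ dKb @ proj @ sb.Vt  # (g, q)
        return m.T.reshape(-1)  # (q,g) flattening to match z.ravel()

    def _g3(self, dKb1, dK2, d2) -> complex:
        """d2 lnS / dX'_c1 dY''_c2 summed over spins."""
        acc = 0.0 + 0.0j
        for sb in self.spins:
            if sb is None:
                continue
            t1 = np.trace(sb.F @ sb.D.conj().T @ d2 @ sb.D)
            m1 = sb.F @ (sb.D.conj().T @ dKb1 @ sb.D)
            m2 = sb.F @ (sb.D.conj().T @ dK2 @ sb.D)
            acc += t1 - np.trace(m1 @ m2)
        return acc

    def _nuclear_coordinate_blocks(self):
        """Lists of (dK, dKb) per stacked coordinate, and d2S lookup."""
        d = self.d
        nc = 3 * self.natom
        trav = self.state.etf_mode == "travelling"
        dKs = [d.dSk_R[c] for c in range(nc)]
        if trav:
            dKs += [d.dSk_P[c] for c in range(nc)]
        dKbs = [m.conj().T for m in dKs]

        def d2(c1, c2):
            t1, i1 = divmod(c1, nc)
            t2, i2 = divmod(c2, nc)
            if not trav:
                return d.d2S_RR[i1, i2]
            blocks = [[d.d2S_RR, d.d2S_RP], [d.d2S_PR, d.d2S_PP]]
            return blocks[t1][t2][i1, i2]

        return dKs, dKbs, d2, (2 * nc if trav else nc)

    def coupling_matrices(self) -> CouplingMatrices:
        nc = 3 * self.natom
        dKs, dKbs, d2look, ntot = self._nuclear_coordinate_blocks()
        g1_blocks = [self._g1(s) for s in range(2)]
        nz = [b.shape[0] for b in g1_blocks]
        C = np.zeros((sum(nz), sum(nz)), dtype=complex)
        C[: nz[0], : nz[0]] = g1_blocks[0]
        C[nz[0]:, nz[0]:] = g1_blocks[1]
        C_X = np.zeros((sum(nz), ntot), dtype=complex)
        for c in range(ntot):
            col = []
            for s in range(2):
                sb = self.spins[s]
                if sb is None or nz[s] == 0:
                    col.append(np.zeros(nz[s], dtype=complex))
                else:
                    col.append(self._g2(s, dKs[c]))
            C_X[:, c] = np.concatenate(col)
        C_R = C_X[:, :nc]
        C_P = (
            C_X[:, nc:]
            if ntot > nc
            else np.zeros((sum(nz), nc), dtype=complex)
        )
        C_XY = np.zeros((ntot, ntot))
        for c1 in range(ntot):
            for c2 in range(ntot):
                C_XY[c1, c2] = -2.0 * np.imag(
                    self._g3(dKbs[c1], dKs[c2], d2look(c1, c2))
                )
        return CouplingMatrices(C=C, C_R=C_R, C_P=C_P, C_XY=C_XY)

    # ---- Pfaffian system ------------------------------------------
    def omega(self) -> np.ndarray:
        """Assemble Omega = K + J over y = (Re z, Im z, R, P)."""
        nc = 3 * self.natom
        dKs, dKbs, d2look, ntot = self._nuclear_coordinate_blocks()
        nz_s = [
            (sb.Vt.shape[1] * sb.n if sb is not None else 0)
            for sb in self.spins
        ]
        nz = sum(nz_s)
        n = 2 * nz + 2 * nc
        K = np.zeros((n, n))

        if nz:
            G1 = np.zeros((nz, nz), dtype=complex)
            G1[: nz_s[0], : nz_s[0]] = self._g1(0)
            G1[nz_s[0]:, nz_s[0]:] = self._g1(1)
            # z-z blocks
            K[:nz, :nz] = -2.0 * np.imag(G1)
            K[:nz, nz: 2 * nz] = -2.0 * np.real(G1)
            K[nz: 2 * nz, :nz] = 2.0 * np.real(G1)
            K[nz: 2 * nz, nz: 2 * nz] = -2.0 * np.imag(G1)
            # z-nuclear blocks
            for c in range(ntot):
                g2 = np.concatenate(
                    [
                        self._g2(s, dKs[c])
                        if self.spins[s] is not None and nz_s[s]
                        else np.zeros(nz_s[s], dtype=complex)
                        for s in range(2)
                    ]
                )
                g2b = np.concatenate(
                    [
                        self._g2b(s, dKbs[c])
                        if self.spins[s] is not None and nz_s[s]
                        else np.zeros(nz_s[s], dtype=complex)
                        for s in range(2)
                    ]
                )
                col = 2 * nz + c
                K[:nz, col] = -2.0 * np.imag(g2)
                K[nz: 2 * nz, col] = 2.0 * np.real(g2)
                K[col, :nz] = -2.0 * np.imag(g2b)
                K[col, nz: 2 * nz] = -2.0 * np.real(g2b)
        # nuclear-nuclear
        for c1 in range(ntot):
            for c2 in range(ntot):
                K[2 * nz + c1, 2 * nz + c2] = -2.0 * np.imag(
                    self._g3(dKbs[c1], dKs[c2], d2look(c1, c2))
                )

        # numerical antisymmetry check (the Euler-Lagrange structure)
        scale = max(1.0, float(np.abs(K).max()))
        asym = float(np.abs(K + K.T).max()) / scale
        if asym > _ANTISYM_TOL:
            raise RuntimeError(
                f"coupling matrix antisymmetry violated ({asym:.2e}); "
                "derivative blocks are inconsistent"
            )
        K = 0.5 * (K - K.T)

        # canonical symplectic block from the P.R' term
        if self.state.etf_mode == "static":
            # static mode has no P-columns in K; extend with zeros
            full = np.zeros((2 * nz + 2 * nc, 2 * nz + 2 * nc))
            full[: 2 * nz + nc, : 2 * nz + nc] = K[
                : 2 * nz + nc, : 2 * nz + nc
            ]
            K = full
        off_R = 2 * nz
        off_P = 2 * nz + nc
        for c in range(nc):
            K[off_R + c, off_P + c] -= 1.0
            K[off_P + c, off_R + c] += 1.0
        return K

    def rhs(self) -> np.ndarray:
        g = self.gradients()
        gx = np.concatenate(
            [2.0 * np.real(m).ravel() for m in g.dE_dz_conj]
        )
        gy = np.concatenate(
            [2.0 * np.imag(m).ravel() for m in g.dE_dz_conj]
        )
        return np.concatenate([gx, gy, g.dE_dR, g.dE_dP])


def solve_eom(state: ThoulessState,
              ders: DerivativeIntegrals | None = None,
              workspace: EOMWorkspace | None = None):
    """Solve Omega y' = dE/dy at one phase-space point.

    Returns (dz_dt per spin, dR_dt, dP_dt, info) with
    info = {'rcond', 'energy'}; dz*/dt is the conjugate of dz/dt by
    construction of the real system.
    """
    ws = workspace or EOMWorkspace(state, ders)
    omega = ws.omega()
    rhs = ws.rhs()
    n = omega.shape[0]
    if n == 0:
        return [state.z[0] * 0, state.z[1] * 0], np.zeros(0), np.zeros(0), {
            "rcond": 1.0, "energy": ws.total_energy()
        }
    lu, piv = lu_factor(omega)
    gecon = lapack.dgecon
    anorm = np.linalg.norm(omega, 1)
    rcond, _ = gecon(lu, anorm, norm="1")
    if not np.isfinite(rcond) or rcond < _RCOND_MIN:
        raise SingularMetricError("singular dynamical system", float(rcond))
    ydot = lu_solve((lu, piv), rhs)

    nz_s = [z.size for z in state.z]
    nz = sum(nz_s)
    nc = 3 * state.nuclear.n_atoms
    dz = []
    for s, off in zip(range(2), (0, nz_s[0])):
        re = ydot[off: off + nz_s[s]]
        im = ydot[nz + off: nz + off + nz_s[s]]
        dz.append((re + 1j * im).reshape(state.z[s].shape))
    dR = ydot[2 * nz: 2 * nz + nc]
    dP = ydot[2 * nz + nc:]
    return dz, dR, dP, {"rcond": float(rcond), "energy": ws.total_energy()}


# ---- convenience single-call operations ----------------------------

def total_energy(state: ThoulessState) -> float:
    return EOMWorkspace(state).total_energy()


def energy_gradients(state: ThoulessState) -> DerivativeBundle:
    return EOMWorkspace(state).gradients()


def coupling_matrices(state: ThoulessState) -> CouplingMatrices:
    return EOMWorkspace(state).coupling_matrices()


def reanchor(state: ThoulessState) -> ThoulessState:
    """Re-express the state over a fresh reference with z = 0.

    The current dynamical occupied orbitals are Lowdin-orthonormalized
    under the overlap at the current geometry and become the new
    reference occupied set; virtuals are rebuilt by projection.  Used as
    an optional control when ||z|| grows large (the Thouless chart is
    local); the represented determinant — and hence all observables — is
    unchanged up to normalization.
    """
    from ..electronic_structure.scf import ReferenceDeterminant

    ws = EOMWorkspace(state)
    K = ws.K
    S = ws.S
    ref = state.reference
    C_new = []
    for s in range(2):
        sb = ws.spins[s]
        n = ref.n_occ[s]
        if sb is None:
            C_new.append(ref.C[s].astype(complex))
            continue
        co = sb.D
        m = co.conj().T @ S @ co
        w, u = np.linalg.eigh(m)
        if w[0] < 1e-12:
            raise SingularMetricError("cannot re-anchor: collapsed DSOs",
                                      float(w[0]))
        co = co @ u @ np.diag(w**-0.5) @ u.conj().T
        # virtuals: S-orthonormal complement of the occupied space
        wS, US = np.linalg.eigh(S)
        X = US @ np.diag(wS**-0.5) @ US.conj().T
        Y = X - co @ (co.conj().T @ S @ X)
        G = Y.conj().T @ S @ Y
        gw, gu = np.linalg.eigh(G)
        idx = np.argsort(gw)[::-1][: K - n]
        V = Y @ gu[:, idx] @ np.diag(gw[idx] ** -0.5)
        C_new.append(np.hstack([co, V]))
    new_ref = ReferenceDeterminant(
        ref.basis,
        (C_new[0], C_new[1]),
        ref.n_occ,
        ref.energies,
        ws.total_energy(),
        True,
        [],
    )
    return ThoulessState(
        new_ref,
        state.nuclear.copy(),
        [np.zeros_like(z) for z in state.z],
        state.time,
        state.etf_mode,
    )


def state_mulliken(state: ThoulessState,
                   ws: EOMWorkspace | None = None) -> np.ndarray:
    """Per-atom Mulliken charges of the normalized Thouless state."""
    ws = ws or EOMWorkspace(state, None)
    dens = [sb.rho for sb in ws.spins if sb is not None]
    return mulliken_charges(
        dens, ws.S, state.basis.ao_atom, state.nuclear.charges
    )
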