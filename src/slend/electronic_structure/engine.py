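"""Reference McMurchie–Davidson integral engine (pure NumPy).

Evaluates overlap, kinetic, nuclear-attraction and electron-repulsion
integrals over contracted Cartesian Gaussians — optionally carrying a
plane-wave phase exp(i k·r) per function (the travelling-basis /
electron-translation-factor mode, where k is the velocity of the
function's nuclear center).  The phase is absorbed into a complex shift
of the Hermite product center; the Hermite recurrences are algebraic in
that center and remain valid, with complex-argument Boys functions in the
Coulomb route.

Functions are represented as lists of ``Term`` tuples so that center- and
momentum-derivatives (which are linear combinations of power-shifted
primitives) flow through every integral type unchanged.  This engine
favours clarity over speed: it is the independent cross-route for the
fast static kernels and the production path for travelling-mode runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSet
from .boys import boys_complex, boys_real

_SCREEN = 1e-18


@dataclass
class Term:
    """One primitive-contraction term of a (possibly derivative) function.

    coeffs are complex per-primitive contraction coefficients (primitive
    norms folded in); phase is the plane-wave vector k of exp(i k.r).
    """

    center: np.ndarray  # (3,)
    powers: np.ndarray  # (3,) int
    alphas: np.ndarray  # (nprim,)
    coeffs: np.ndarray  # (nprim,) complex
    phase: np.ndarray  # (3,)


GenFn = list  # list[Term]


def basis_terms(
    basis: BasisSet,
    positions: np.ndarray,
    velocities: np.ndarray | None = None,
) -> list[GenFn]:
    """Expand a basis at given atom positions (Bohr) into term lists.

    ``velocities`` (natom, 3) switches on travelling mode: each function
    acquires the plane-wave phase of its atom's velocity.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    fns: list[GenFn] = []
    for f in basis.functions:
        k = (
            np.zeros(3)
            if velocities is None
            else np.asarray(velocities, float).reshape(-1, 3)[f.atom_index]
        )
        fns.append(
            [
                Term(
                    positions[f.atom_index].copy(),
                    np.array(f.powers, int),
                    f.alphas.copy(),
                    f.coeffs.astype(complex),
                    k.copy(),
                )
            ]
        )
    return fns


def center_deriv(fn: GenFn, d: int) -> GenFn:
    """d/d(center_d) of a generalized function (phase held fixed)."""
    out: GenFn = []
    for t in fn:
        up = t.powers.copy()
        up[d] += 1
        out.append(Term(t.center, up, t.alphas, 2.0 * t.alphas * t.coeffs,
                        t.phase))
        if t.powers[d] > 0:
            dn = t.powers.copy()
            dn[d] -= 1
            out.append(Term(t.center, dn, t.alphas,
                            -float(t.powers[d]) * t.coeffs, t.phase))
    return out


def momentum_deriv(fn: GenFn, d: int, mass: float) -> GenFn:
    """d/d(P_d) of a travelling function: phase k = P/M gives i r_d / M.

    r_d f = (r_d - A_d) f + A_d f, i.e. a power raise plus the base term.
    """
    out: GenFn = []
    for t in fn:
        up = t.powers.copy()
        up[d] += 1
        out.append(Term(t.center, up, t.alphas, (1j / mass) * t.coeffs,
                        t.phase))
        out.append(Term(t.center, t.powers.copy(), t.alphas,
                        (1j * t.center[d] / mass) * t.coeffs, t.phase))
    return out


def grad_terms(fn: GenFn, d: int) -> GenFn:
    """d/d(r_d) of the function itself (for kinetic via grad.grad).

    Includes the phase derivative i k_d."""
    out: GenFn = []
    for t in fn:
        up = t.powers.copy()
        up[d] += 1
        out.append(Term(t.center, up, t.alphas, -2.0 * t.alphas * t.coeffs,
                        t.phase))
        if t.powers[d] > 0:
            dn = t.powers.copy()
            dn[d] -= 1
            out.append(Term(t.center, dn, t.alphas,
                            float(t.powers[d]) * t.coeffs, t.phase))
        if t.phase[d] != 0.0:
            out.append(Term(t.center, t.powers.copy(), t.alphas,
                            1j * t.phase[d] * t.coeffs, t.phase))
    return out


def _e_tables(imax, jmax, PA, PB, oo2p):
    """Hermite expansion coefficients E[i, j, t] per dimension, vectorized
    over the trailing primitive-pair axis.  E[0,0,0] = 1."""
    n = PA.shape[-1]
    E = np.zeros((imax + 1, jmax + 1, imax + jmax + 1, n), dtype=complex)
    E[0, 0, 0] = 1.0
    for i in range(imax):
        for t in range(i + 2):
            val = 0.0
            if t - 1 >= 0:
                val = val + oo2p * E[i, 0, t - 1]
            if t <= i:
                val = val + PA * E[i, 0, t]
            if t + 1 <= i:
                val = val + (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = val
    for i in range(imax + 1):
        for j in range(jmax):
            for t in range(i + j + 2):
                val = 0.0
                if t - 1 >= 0:
                    val = val + oo2p * E[i, j, t - 1]
                if t <= i + j:
                    val = val + PB * E[i, j, t]
                if t + 1 <= i + j:
                    val = val + (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = val
    return E


class _PairData:
    """Flattened primitive-pair quantities for one (bra-term, ket-term)."""

    __slots__ = ("c", "p", "P", "E", "ib", "ik", "n")

    def __init__(self, bra: Term, ket: Term):
        a = bra.alphas[:, None]
        b = ket.alphas[None, :]
        p = (a + b).ravel()
        A, B = bra.center, ket.center
        ab2 = float(np.dot(A - B, A - B))
        mu = (a * b).ravel() / p
        pref = np.exp(-mu * ab2)
        # phase of the product: conj(bra) * ket
        kappa = ket.phase - bra.phase
        P = (a[..., None] * A + b[..., None] * B).reshape(-1, 3) / p[:, None]
        if np.any(kappa):
            pref = pref * np.exp(
                1j * (P @ kappa) - float(kappa @ kappa) / (4.0 * p)
            )
            Pt = P + 1j * kappa[None, :] / (2.0 * p[:, None])
        else:
            Pt = P.astype(complex)
        cc = (np.conj(bra.coeffs)[:, None] * ket.coeffs[None, :]).ravel()
        keep = np.abs(pref) * np.abs(cc) > _SCREEN
        self.n = int(keep.sum())
        self.c = (cc * pref)[keep]
        self.p = p[keep]
        self.P = Pt[keep]
        self.ib = bra.powers
        self.ik = ket.powers
        oo2p = 1.0 / (2.0 * self.p)
        self.E = [
            _e_tables(
                int(self.ib[d]),
                int(self.ik[d]),
                self.P[:, d] - A[d],
                self.P[:, d] - B[d],
                oo2p,
            )
            for d in range(3)
        ]


def _pair_overlap(pd: _PairData) -> complex:
    if pd.n == 0:
        return 0.0 + 0.0j
    val = (
        pd.E[0][pd.ib[0], pd.ik[0], 0]
        * pd.E[1][pd.ib[1], pd.ik[1], 0]
        * pd.E[2][pd.ib[2], pd.ik[2], 0]
    )
    return complex(np.sum(pd.c * val * (np.pi / pd.p) ** 1.5))


def _hermite_density(pd: _PairData) -> np.ndarray:
    """Lambda[t, u, v, npair] Hermite expansion of the pair density."""
    i, j = pd.ib, pd.ik
    L = int(i.sum() + j.sum())
    lam = np.zeros((L + 1, L + 1, L + 1, pd.n), dtype=complex)
    for t in range(i[0] + j[0] + 1):
        ex = pd.E[0][i[0], j[0], t]
        for u in range(i[1] + j[1] + 1):
            ey = pd.E[1][i[1], j[1], u]
            for v in range(i[2] + j[2] + 1):
                lam[t, u, v] = ex * ey * pd.E[2][i[2], j[2], v]
    return lam


def _r_tensor(L: int, alpha: np.ndarray, X: np.ndarray, complex_mode: bool
              ) -> np.ndarray:
    """Hermite-Coulomb tensor R[t, u, v, n] (auxiliary order folded in)."""
    T = alpha * np.einsum("nd,nd->n", X, X)
    if complex_mode:
        F = boys_complex(L, T)
    else:
        F = boys_real(L, np.real(T)).astype(complex)
    n = alpha.shape[0]
    R = np.zeros((L + 1, L + 1, L + 1, L + 1, n), dtype=complex)
    fac = np.ones(n, dtype=complex)
    for m in range(L + 1):
        R[m, 0, 0, 0] = fac * F[m]
        fac = fac * (-2.0 * alpha)
    for m in range(L - 1, -1, -1):
        top = L - m
        for t in range(top + 1):
            for u in range(top - t + 1):
                for v in range(top - t - u + 1):
                    if t == u == v == 0:
                        continue
                    if t > 0:
                        val = X[:, 0] * R[m + 1, t - 1, u, v]
                        if t > 1:
                            val = val + (t - 1) * R[m + 1, t - 2, u, v]
                    elif u > 0:
                        val = X[:, 1] * R[m + 1, t, u - 1, v]
                        if u > 1:
                            val = val + (u - 1) * R[m + 1, t, u - 2, v]
                    else:
                        val = X[:, 2] * R[m + 1, t, u, v - 1]
                        if v > 1:
                            val = val + (v - 1) * R[m + 1, t, u, v - 2]
                    R[m, t, u, v] = val
    return R[0]


def _pair_nuclear(pd: _PairData, charges: np.ndarray, coords: np.ndarray,
                  complex_mode: bool) -> complex:
    if pd.n == 0:
        return 0.0 + 0.0j
    lam = _hermite_density(pd)
    L = lam.shape[0] - 1
    total = 0.0 + 0.0j
    for zc, C in zip(charges, coords):
        X = pd.P - C[None, :]
        cplx = complex_mode or bool(np.any(np.imag(pd.P)))
        R = _r_tensor(L, pd.p.astype(complex), X, cplx)
        acc = np.zeros(pd.n, dtype=complex)
        for t in range(L + 1):
            for u in range(L + 1 - t):
                for v in range(L + 1 - t - u):
                    acc = acc + lam[t, u, v] * R[t, u, v]
        total = total - zc * np.sum(pd.c * (2.0 * np.pi / pd.p) * acc)
    return complex(total)


def _quartet_from_pairs(pd1: _PairData, lam1, pd2: _PairData, lam2) -> complex:
    if pd1.n == 0 or pd2.n == 0:
        return 0.0 + 0.0j
    L1 = lam1.shape[0] - 1
    L2 = lam2.shape[0] - 1
    p = pd1.p[:, None]
    q = pd2.p[None, :]
    alpha = (p * q / (p + q)).ravel()
    X = (pd1.P[:, None, :] - pd2.P[None, :, :]).reshape(-1, 3)
    cplx = bool(np.any(np.imag(X)))
    R = _r_tensor(L1 + L2, alpha.astype(complex), X, cplx)
    pref = (2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))).ravel() * (
        pd1.c[:, None] * pd2.c[None, :]
    ).ravel()
    acc = np.zeros(alpha.shape[0], dtype=complex)
    for t in range(L1 + 1):
        for u in range(L1 + 1 - t):
            for v in range(L1 + 1 - t - u):
                l1 = lam1[t, u, v][:, None]
                for tt in range(L2 + 1):
                    for uu in range(L2 + 1 - tt):
                        for vv in range(L2 + 1 - tt - uu):
                            sgn = (-1.0) ** (tt + uu + vv)
                            acc = acc + sgn * (
                                l1 * lam2[tt, uu, vv][None, :]
                            ).ravel() * R[t + tt, u + uu, v + vv]
    return complex(np.sum(pref * acc))


def overlap(bra: GenFn, ket: GenFn) -> complex:
    return sum(
        _pair_overlap(_PairData(b, k)) for b in bra for k in ket
    )


def overlap_matrix(bras: list[GenFn], kets: list[GenFn]) -> np.ndarray:
    out = np.empty((len(bras), len(kets)), dtype=complex)
    for i, b in enumerate(bras):
        for j, k in enumerate(kets):
            out[i, j] = overlap(b, k)
    return out


def kinetic(bra: GenFn, ket: GenFn) -> complex:
    """T via the symmetric gradient–gradient form (phase-aware)."""
    val = 0.0 + 0.0j
    for d in range(3):
        val += 0.5 * overlap(grad_terms(bra, d), grad_terms(ket, d))
    return val


def kinetic_matrix(bras: list[GenFn], kets: list[GenFn]) -> np.ndarray:
    out = np.empty((len(bras), len(kets)), dtype=complex)
    for i, b in enumerate(bras):
        for j, k in enumerate(kets):
            out[i, j] = kinetic(b, k)
    return out


def nuclear(bra: GenFn, ket: GenFn, charges, coords,
            complex_mode: bool = False) -> complex:
    charges = np.asarray(charges, float)
    coords = np.asarray(coords, float).reshape(-1, 3)
    return sum(
        _pair_nuclear(_PairData(b, k), charges, coords, complex_mode)
        for b in bra
        for k in ket
    )


def _pair_nuclear_center_grad(pd: _PairData, zc: float, C: np.ndarray,
                              d: int) -> complex:
    """<bra| d/dC_d (-zc/|r-C|) |ket> via the Hermite index raise."""
    if pd.n == 0:
        return 0.0 + 0.0j
    lam = _hermite_density(pd)
    L = lam.shape[0] - 1
    X = pd.P - C[None, :]
    cplx = bool(np.any(np.imag(pd.P)))
    R = _r_tensor(L + 1, pd.p.astype(complex), X, cplx)
    off = [0, 0, 0]
    off[d] = 1
    acc = np.zeros(pd.n, dtype=complex)
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for v in range(L + 1 - t - u):
                acc = acc + lam[t, u, v] * R[t + off[0], u + off[1],
                                             v + off[2]]
    # dV/dC_d = -zc * (2pi/p) * (-R_{+e_d}) contraction
    return complex(zc * np.sum(pd.c * (2.0 * np.pi / pd.p) * acc))


def nuclear_center_grad(bra: GenFn, ket: GenFn, zc: float, C, d: int
                        ) -> complex:
    C = np.asarray(C, float).reshape(3)
    return sum(
        _pair_nuclear_center_grad(_PairData(b, k), float(zc), C, d)
        for b in bra
        for k in ket
    )


def nuclear_matrix(bras, kets, charges, coords, complex_mode=False):
    out = np.empty((len(bras), len(kets)), dtype=complex)
    for i, b in enumerate(bras):
        for j, k in enumerate(kets):
            out[i, j] = nuclear(b, k, charges, coords, complex_mode)
    return out


def eri(bra1: GenFn, ket1: GenFn, bra2: GenFn, ket2: GenFn) -> complex:
    """(mu nu | lambda sigma) in chemists' notation; bra1/bra2 conjugated."""
    total = 0.0 + 0.0j
    for b1 in bra1:
        for k1 in ket1:
            pd1 = _PairData(b1, k1)
            if pd1.n == 0:
                continue
            lam1 = _hermite_density(pd1)
            for b2 in bra2:
                for k2 in ket2:
                    pd2 = _PairData(b2, k2)
                    if pd2.n == 0:
                        continue
                    total = total + _quartet_from_pairs(
                        pd1, lam1, pd2, _hermite_density(pd2)
                    )
    return total


def eri_tensor(fns: list[GenFn]) -> np.ndarray:
    """Full (K,K,K,K) chemists'-notation tensor.

    Pair Hermite densities are precomputed once; the (12|34) <-> (34|12)
    swap symmetry (valid also with phases) halves the quartet loop.
    """
    K = len(fns)
    pairs: list[list[tuple[_PairData, np.ndarray]]] = []
    flat_idx = []
    for m in range(K):
        for n in range(K):
            pds = []
            for b in fns[m]:
                for k in fns[n]:
                    pd = _PairData(b, k)
                    if pd.n:
                        pds.append((pd, _hermite_density(pd)))
            pairs.append(pds)
            flat_idx.append((m, n))
    out = np.zeros((K, K, K, K), dtype=complex)
    npair = len(pairs)
    for i1 in range(npair):
        m, n = flat_idx[i1]
        for i2 in range(i1, npair):
            l, s = flat_idx[i2]
            val = 0.0 + 0.0j
            for pd1, lam1 in pairs[i1]:
                for pd2, lam2 in pairs[i2]:
                    val += _quartet_from_pairs(pd1, lam1, pd2, lam2)
            out[m, n, l, s] = val
            out[l, s, m, n] = val
    return out
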