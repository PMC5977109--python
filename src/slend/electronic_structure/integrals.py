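"""Integral evaluation front end.

``compute_integrals`` returns the value-level integral set used by the
SCF; ``compute_derivative_integrals`` additionally returns every
derivative block the dynamical equations need.  Static mode dispatches to
the numba kernels (:mod:`fast`); travelling mode — basis functions
carrying the plane-wave momentum phase of their center — goes through the
reference engine, whose generalized-term machinery handles the momentum
derivatives that have no standard-backend equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import engine, fast
from .basis import BasisSet

#: Below this smallest overlap eigenvalue the basis is flagged as
#: (near-)linearly dependent.
LINDEP_THRESHOLD = 1e-8


class LinearDependenceWarning(UserWarning):
    pass


def flatten_basis(basis: BasisSet, positions: np.ndarray):
    """Flat arrays for the numba kernels."""
    K = basis.K
    positions = np.asarray(positions, float).reshape(-1, 3)
    centers = np.empty((K, 3))
    powers = np.empty((K, 3), dtype=np.int64)
    ao_atom = np.empty(K, dtype=np.int64)
    alphas = []
    coefs = []
    pptr = np.zeros(K + 1, dtype=np.int64)
    for mu, f in enumerate(basis.functions):
        centers[mu] = positions[f.atom_index]
        powers[mu] = f.powers
        ao_atom[mu] = f.atom_index
        alphas.append(f.alphas)
        coefs.append(f.coeffs)
        pptr[mu + 1] = pptr[mu] + len(f.alphas)
    return (
        centers,
        powers,
        pptr,
        np.concatenate(alphas),
        np.concatenate(coefs),
        ao_atom,
    )


@dataclass
class IntegralSet:
    """Value-level AO integrals at one nuclear configuration."""

    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    eri: np.ndarray | None
    vnn: float
    mode: str
    overlap_min_eig: float = field(default=np.nan)

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.V


@dataclass
class DerivativeIntegrals:
    """AO integrals plus the derivative blocks the EOM assembly needs.

    Coordinate index c runs over the 3*natom flattened (atom-major)
    nuclear coordinates.  ``dSk_R[c]`` is the ket-side overlap derivative
    <mu | d nu/dR_c>; ``d2S_RR[c1, c2]`` is <d mu/dR_c1 | d nu/dR_c2>;
    ``dh_R`` / ``deri_R`` / ``dvnn`` are full derivatives.  The ``*_P``
    blocks are momentum derivatives and are None in static mode.
    """

    values: IntegralSet
    dSk_R: np.ndarray
    d2S_RR: np.ndarray
    dh_R: np.ndarray
    deri_R: np.ndarray | None
    dvnn: np.ndarray
    dSk_P: np.ndarray | None = None
    d2S_RP: np.ndarray | None = None
    d2S_PR: np.ndarray | None = None
    d2S_PP: np.ndarray | None = None
    dh_P: np.ndarray | None = None
    deri_P: np.ndarray | None = None


def nuclear_repulsion(charges: np.ndarray, positions: np.ndarray) -> float:
    e = 0.0
    n = len(charges)
    for i in range(n):
        for j in range(i + 1, n):
            e += charges[i] * charges[j] / np.linalg.norm(
                positions[i] - positions[j]
            )
    return e


def nuclear_repulsion_grad(charges, positions) -> np.ndarray:
    n = len(charges)
    g = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = positions[i] - positions[j]
            g[i] -= charges[i] * charges[j] * d / np.linalg.norm(d) ** 3
    return g.reshape(-1)


def _check_lindep(S: np.ndarray) -> float:
    w = np.linalg.eigvalsh(0.5 * (S + S.conj().T))
    wmin = float(w[0])
    if wmin < LINDEP_THRESHOLD:
        warnings.warn(
            f"near-linear dependence: smallest overlap eigenvalue {wmin:.3e}",
            LinearDependenceWarning,
            stacklevel=3,
        )
    return wmin


def compute_integrals(
    basis: BasisSet,
    positions: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
    mode: str = "static",
    need_eri: bool = True,
) -> IntegralSet:
    """AO integrals at given positions (defaults to the system geometry).

    mode 'static': real standard integrals; mode 'travelling': each basis
    function carries exp(i v.r) with v the velocity of its center, giving
    complex Hermitian S and core blocks (momenta of zero reduce exactly to
    the static result).
    """
    if mode not in ("static", "travelling"):
        raise ValueError(f"unknown etf mode {mode!r}")
    system = basis.system
    if positions is None:
        positions = system.positions
    positions = np.asarray(positions, float).reshape(-1, 3)
    charges = system.charges
    vnn = nuclear_repulsion(charges, positions)

    if mode == "static":
        centers, powers, pptr, pal, pco, ao_atom = flatten_basis(
            basis, positions
        )
        S, T, V, *_ = fast.one_electron(
            centers, powers, pptr, pal, pco, ao_atom, positions, charges,
            False,
        )
        eri = None
        if need_eri:
            eri, _ = fast.eri_block(
                centers, powers, pptr, pal, pco, ao_atom, len(charges),
                False,
            )
        out = IntegralSet(S, T, V, eri, vnn, mode)
    else:
        if velocities is None:
            velocities = np.zeros_like(positions)
        fns = engine.basis_terms(basis, positions, velocities)
        S = engine.overlap_matrix(fns, fns)
        T = engine.kinetic_matrix(fns, fns)
        V = engine.nuclear_matrix(fns, fns, charges, positions)
        eri = engine.eri_tensor(fns) if need_eri else None
        out = IntegralSet(S, T, V, eri, vnn, mode)
    out.overlap_min_eig = _check_lindep(out.S)
    return out


def _engine_coordinate_matrix(fns, builder, ao_atom, atom, d, side, other_fns):
    """Matrix of <mu|D nu> (side='ket') or <D mu|nu> (side='bra') where D
    is ``builder`` applied in dimension d to functions on ``atom``."""
    K = len(fns)
    out = np.zeros((K, K), dtype=complex)
    for idx in range(K):
        if ao_atom[idx] != atom:
            continue
        dfn = builder(fns[idx], d)
        for jdx in range(K):
            if side == "ket":
                out[jdx, idx] = engine.overlap(other_fns[jdx], dfn)
            else:
                out[idx, jdx] = engine.overlap(dfn, other_fns[jdx])
    return out


def compute_derivative_integrals(
    basis: BasisSet,
    positions: np.ndarray,
    velocities: np.ndarray | None = None,
    mode: str = "static",
    need_eri: bool = True,
) -> DerivativeIntegrals:
    """Everything the dynamical equations need at one phase-space point."""
    system = basis.system
    positions = np.asarray(positions, float).reshape(-1, 3)
    natom = system.n_atoms
    nc = 3 * natom
    charges = system.charges
    K = basis.K
    values = None

    if mode == "static":
        centers, powers, pptr, pal, pco, ao_atom = flatten_basis(
            basis, positions
        )
        S, T, V, dSk, dTf, dVf, d2S = fast.one_electron(
            centers, powers, pptr, pal, pco, ao_atom, positions, charges,
            True,
        )
        if need_eri:
            eri_t, deri = fast.eri_block(
                centers, powers, pptr, pal, pco, ao_atom, natom, True
            )
            deri_R = deri.reshape(nc, K, K, K, K)
        else:
            eri_t, deri_R = None, None
        values = IntegralSet(
            S, T, V, eri_t, nuclear_repulsion(charges, positions), mode
        )
        values.overlap_min_eig = _check_lindep(S)
        return DerivativeIntegrals(
            values=values,
            dSk_R=dSk.reshape(nc, K, K),
            d2S_RR=d2S.reshape(nc, 3 * natom, K, K).reshape(nc, nc, K, K),
            dh_R=(dTf + dVf).reshape(nc, K, K),
            deri_R=deri_R,
            dvnn=nuclear_repulsion_grad(charges, positions),
        )

    # ---- travelling mode (reference engine) ----
    if velocities is None:
        velocities = np.zeros_like(positions)
    masses = system.masses
    fns = engine.basis_terms(basis, positions, velocities)
    ao_atom = basis.ao_atom
    values = compute_integrals(
        basis, positions, velocities, mode, need_eri=need_eri
    )

    def cderiv(fn, d):
        return engine.center_deriv(fn, d)

    dSk_R = np.zeros((nc, K, K), dtype=complex)
    dSk_P = np.zeros((nc, K, K), dtype=complex)
    for a in range(natom):
        def pderiv(fn, d, _m=float(masses[a])):
            return engine.momentum_deriv(fn, d, _m)

        for d in range(3):
            c = 3 * a + d
            dSk_R[c] = _engine_coordinate_matrix(
                fns, cderiv, ao_atom, a, d, "ket", fns
            )
            dSk_P[c] = _engine_coordinate_matrix(
                fns, pderiv, ao_atom, a, d, "ket", fns
            )

    def _second(builder_b, builder_k, mass_of=None):
        out = np.zeros((nc, nc, K, K), dtype=complex)
        dfns_b = {}
        dfns_k = {}
        for a in range(natom):
            for d in range(3):
                for mu in range(K):
                    if ao_atom[mu] == a:
                        dfns_b[(3 * a + d, mu)] = builder_b(
                            fns[mu], d, float(masses[a])
                        )
                        dfns_k[(3 * a + d, mu)] = builder_k(
                            fns[mu], d, float(masses[a])
                        )
        for (c1, mu), bfn in dfns_b.items():
            for (c2, nu), kfn in dfns_k.items():
                out[c1, c2, mu, nu] = engine.overlap(bfn, kfn)
        return out

    def _cd(fn, d, m):
        return engine.center_deriv(fn, d)

    def _pd(fn, d, m):
        return engine.momentum_deriv(fn, d, m)

    d2S_RR = _second(_cd, _cd)
    d2S_RP = _second(_cd, _pd)
    d2S_PR = _second(_pd, _cd)
    d2S_PP = _second(_pd, _pd)

    # full derivatives of h wrt R and P
    dh_R = np.zeros((nc, K, K), dtype=complex)
    dh_P = np.zeros((nc, K, K), dtype=complex)
    for a in range(natom):
        for d in range(3):
            c = 3 * a + d
            for mu in range(K):
                mu_on = ao_atom[mu] == a
                for nu in range(K):
                    nu_on = ao_atom[nu] == a
                    acc = 0.0 + 0.0j
                    accp = 0.0 + 0.0j
                    if mu_on:
                        dfn = engine.center_deriv(fns[mu], d)
                        acc += engine.kinetic(dfn, fns[nu])
                        acc += engine.nuclear(
                            dfn, fns[nu], charges, positions
                        )
                        pfn = engine.momentum_deriv(
                            fns[mu], d, float(masses[a])
                        )
                        accp += engine.kinetic(pfn, fns[nu])
                        accp += engine.nuclear(
                            pfn, fns[nu], charges, positions
                        )
                    if nu_on:
                        dfn = engine.center_deriv(fns[nu], d)
                        acc += engine.kinetic(fns[mu], dfn)
                        acc += engine.nuclear(
                            fns[mu], dfn, charges, positions
                        )
                        pfn = engine.momentum_deriv(
                            fns[nu], d, float(masses[a])
                        )
                        accp += engine.kinetic(fns[mu], pfn)
                        accp += engine.nuclear(
                            fns[mu], pfn, charges, positions
                        )
                    # operator (attraction-center) derivative
                    acc += engine.nuclear_center_grad(
                        fns[mu], fns[nu], charges[a], positions[a], d
                    )
                    dh_R[c, mu, nu] = acc
                    dh_P[c, mu, nu] = accp

    deri_R = None
    deri_P = None
    if need_eri:
        deri_R = np.zeros((nc, K, K, K, K), dtype=complex)
        deri_P = np.zeros((nc, K, K, K, K), dtype=complex)
        for a in range(natom):
            for d in range(3):
                c = 3 * a + d
                for mu in range(K):
                    if ao_atom[mu] != a:
                        continue
                    dfn = engine.center_deriv(fns[mu], d)
                    pfn = engine.momentum_deriv(fns[mu], d, float(masses[a]))
                    for nu in range(K):
                        for lam in range(K):
                            for sig in range(K):
                                deri_R[c, mu, nu, lam, sig] += engine.eri(
                                    dfn, fns[nu], fns[lam], fns[sig]
                                )
                                deri_P[c, mu, nu, lam, sig] += engine.eri(
                                    pfn, fns[nu], fns[lam], fns[sig]
                                )
        # slot-2 (ket of the bra pair) derivatives, computed directly:
        for a in range(natom):
            for d in range(3):
                c = 3 * a + d
                for nu in range(K):
                    if ao_atom[nu] != a:
                        continue
                    dfn = engine.center_deriv(fns[nu], d)
                    pfn = engine.momentum_deriv(fns[nu], d, float(masses[a]))
                    for mu in range(K):
                        for lam in range(K):
                            for sig in range(K):
                                deri_R[c, mu, nu, lam, sig] += engine.eri(
                                    fns[mu], dfn, fns[lam], fns[sig]
                                )
                                deri_P[c, mu, nu, lam, sig] += engine.eri(
                                    fns[mu], pfn, fns[lam], fns[sig]
                                )
        # ket-pair slots via (12|34) = (34|12)
        for c in range(nc):
            half = deri_R[c].copy()
            deri_R[c] = half + np.transpose(half, (2, 3, 0, 1))
            halfp = deri_P[c].copy()
            deri_P[c] = halfp + np.transpose(halfp, (2, 3, 0, 1))

    return DerivativeIntegrals(
        values=values,
        dSk_R=dSk_R,
        d2S_RR=d2S_RR,
        dh_R=dh_R,
        deri_R=deri_R,
        dvnn=nuclear_repulsion_grad(charges, positions),
        dSk_P=dSk_P,
        d2S_RP=d2S_RP,
        d2S_PR=d2S_PR,
        d2S_PP=d2S_PP,
        dh_P=dh_P,
        deri_P=deri_P,
    )
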