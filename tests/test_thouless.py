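"""Thouless state algebra: overlaps, energies, gradients, couplings.

The finite-difference oracles differentiate ln S and E_Total computed by
the independent mixed-overlap route (engine-based), while the analytic
blocks come from the dense matrix-calculus formulas — two genuinely
different code paths.
"""

import numpy as np
import pytest

from slend.chem_system import Atom, MolecularSystem, PROTON_MASS_AU
from slend.electronic_structure.scf import run_uhf
from slend.thouless_dynamics import (
    EOMWorkspace,
    NuclearConfiguration,
    ThoulessState,
    coupling_matrices,
    energy_gradients,
    nuclear_from_system,
    thouless_overlap,
    total_energy,
)

from conftest import zero_state


def _random_state(det, seed=0, z_scale=0.15, p_scale=1.0, mode="static"):
    rng = np.random.default_rng(seed)
    K = det.basis.K
    z = []
    for s in range(2):
        n = det.n_occ[s]
        z.append(
            z_scale
            * (
                rng.standard_normal((K - n, n))
                + 1j * rng.standard_normal((K - n, n))
            )
        )
    sys = det.basis.system
    nuc = NuclearConfiguration(
        sys.positions,
        p_scale * rng.standard_normal((sys.n_atoms, 3)),
        sys.masses,
        sys.charges,
    )
    return ThoulessState(det, nuc, z, etf_mode=mode)


# ---- overlaps -------------------------------------------------------

def test_reference_overlap_is_one(h2_det):
    st = zero_state(h2_det)
    assert thouless_overlap(st, st) == pytest.approx(1.0, abs=1e-12)


def test_one_electron_k2_overlap_closed_form(h2p_det):
    """For one electron in K=2 the diagonal overlap is 1 + |w|^2."""
    w = 0.3 - 0.45j
    st = zero_state(h2p_det)
    st.z[0][0, 0] = w
    got = thouless_overlap(st, st)
    assert got == pytest.approx(1.0 + abs(w) ** 2, abs=1e-12)


def test_overlap_modulus_invariant_under_occupied_phase(h2_det):
    """A global phase on the reference occupied orbitals leaves |S|
    unchanged (determinant property)."""
    st = _random_state(h2_det, seed=1)
    base = abs(thouless_overlap(st, st))
    det2 = h2_det.spin_flipped().spin_flipped()  # deep-ish copy
    C0 = det2.C[0].copy()
    # a sign flip is the phase available to real-stored orbitals
    C0[:, : det2.n_occ[0]] *= -1
    det3 = type(det2)(
        det2.basis, (C0, det2.C[1]), det2.n_occ, det2.energies,
        det2.energy,
    )
    st2 = ThoulessState(det3, st.nuclear.copy(), [z.copy() for z in st.z])
    assert abs(thouless_overlap(st2, st2)) == pytest.approx(base, rel=1e-10)


# ---- energies -------------------------------------------------------

def test_energy_at_reference_equals_scf(h2_det, h2o_det):
    for det in (h2_det, h2o_det):
        st = zero_state(det)
        assert total_energy(st) == pytest.approx(det.energy, abs=1e-10)


def test_energy_is_real_valued(h2_det):
    st = _random_state(h2_det, seed=2)
    e = total_energy(st)
    assert isinstance(e, float) and np.isfinite(e)


def test_bare_proton_energy_is_kinetic():
    prot = MolecularSystem(
        [Atom("H", [0, 0, 0], mass=PROTON_MASS_AU)], 1, 1
    )
    det = run_uhf(prot, "sto-3g")
    v = 2.0
    nuc = NuclearConfiguration(
        [[0, 0, 0]], [[PROTON_MASS_AU * v, 0, 0]], [PROTON_MASS_AU], [1.0]
    )
    st = ThoulessState(det, nuc, [np.zeros((1, 0)), np.zeros((1, 0))])
    assert total_energy(st) == pytest.approx(
        0.5 * PROTON_MASS_AU * v * v, rel=1e-12
    )


def test_energy_invariant_under_occupied_mixing(h2o_det):
    """Mixing the reference occupied orbitals among themselves changes z
    coordinates but not the represented determinant at z=0."""
    st = zero_state(h2o_det)
    e0 = total_energy(st)
    n = h2o_det.n_occ[0]
    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    C0 = h2o_det.C[0].copy()
    C0[:, :n] = C0[:, :n] @ q
    det2 = type(h2o_det)(
        h2o_det.basis, (C0, h2o_det.C[1]), h2o_det.n_occ,
        h2o_det.energies, h2o_det.energy,
    )
    st2 = zero_state(det2)
    assert total_energy(st2) == pytest.approx(e0, abs=1e-10)


# ---- gradients ------------------------------------------------------

def test_brillouin_condition(h2o_det):
    st = zero_state(h2o_det)
    g = energy_gradients(st)
    for s in range(2):
        assert np.abs(g.dE_dz_conj[s]).max() < 1e-7


def test_static_mode_momentum_gradient_is_velocity(h2_det):
    st = _random_state(h2_det, seed=4)
    g = energy_gradients(st)
    expect = (
        st.nuclear.momenta / st.nuclear.masses[:, None]
    ).ravel()
    assert np.abs(g.dE_dP - expect).max() == 0.0


@pytest.mark.parametrize("det_name", ["h2p_det", "h2_det"])
def test_energy_gradients_match_finite_differences(det_name, request):
    det = request.getfixturevalue(det_name)
    st = _random_state(det, seed=5)
    g = energy_gradients(st)
    eps = 1e-5
    nc = 3 * st.nuclear.n_atoms
    fd = np.zeros(nc)
    for c in range(nc):
        a, d = divmod(c, 3)
        sp = st.copy()
        sp.nuclear.positions[a, d] += eps
        sm = st.copy()
        sm.nuclear.positions[a, d] -= eps
        fd[c] = (total_energy(sp) - total_energy(sm)) / (2 * eps)
    scale = max(1.0, np.abs(fd).max())
    assert np.abs(g.dE_dR - fd).max() / scale < 1e-6
    # z gradients against real/imag finite differences
    for s in range(2):
        if st.z[s].size == 0:
            continue
        sp = st.copy()
        sp.z[s][0, 0] += eps
        sm = st.copy()
        sm.z[s][0, 0] -= eps
        fdx = (total_energy(sp) - total_energy(sm)) / (2 * eps)
        assert 2 * np.real(g.dE_dz_conj[s][0, 0]) == pytest.approx(
            fdx, rel=1e-6, abs=1e-9
        )
        sp = st.copy()
        sp.z[s][0, 0] += 1j * eps
        sm = st.copy()
        sm.z[s][0, 0] -= 1j * eps
        fdy = (total_energy(sp) - total_energy(sm)) / (2 * eps)
        assert 2 * np.imag(g.dE_dz_conj[s][0, 0]) == pytest.approx(
            fdy, rel=1e-6, abs=1e-9
        )


# ---- coupling matrices ---------------------------------------------

def test_metric_is_identity_at_reference(h2o_det):
    st = zero_state(h2o_det)
    cm = coupling_matrices(st)
    n = cm.C.shape[0]
    assert np.abs(cm.C - np.eye(n)).max() < 1e-10


def test_static_mode_momentum_couplings_vanish(h2_det):
    st = _random_state(h2_det, seed=6)
    cm = coupling_matrices(st)
    assert np.abs(cm.C_P).max() == 0.0
    nc = 3 * st.nuclear.n_atoms
    assert cm.C_XY.shape == (nc, nc)  # no P block in static mode


def _lnS(bra, ket):
    return np.log(thouless_overlap(bra, ket))


def _fd_second(st, bra_mut, ket_mut, eps):
    vals = {}
    for sb in (eps, -eps):
        for sk in (eps, -eps):
            bra = st.copy()
            bra_mut(bra, sb)
            ket = st.copy()
            ket_mut(ket, sk)
            vals[(sb, sk)] = _lnS(bra, ket)
    return (
        vals[(eps, eps)] - vals[(eps, -eps)] - vals[(-eps, eps)]
        + vals[(-eps, -eps)]
    ) / (4 * eps * eps)


@pytest.mark.parametrize("det_name", ["h2p_det", "h2_det"])
def test_couplings_match_lnS_finite_differences(det_name, request):
    """Every Eq.-style coupling block equals a central finite difference
    of ln S computed through the independent mixed-overlap route."""
    det = request.getfixturevalue(det_name)
    st = _random_state(det, seed=7)
    ws = EOMWorkspace(st)
    cm = ws.coupling_matrices()
    eps = 1e-4

    # C block (z'* x z), first element of spin alpha
    fd = _fd_second(
        st,
        lambda s, e: s.z[0].__setitem__((0, 0), s.z[0][0, 0] + e),
        lambda s, e: s.z[0].__setitem__((0, 0), s.z[0][0, 0] + e),
        eps,
    )
    assert cm.C[0, 0] == pytest.approx(fd, rel=2e-6, abs=2e-6)

    # C_R block (z'* x R), coordinate 2
    c = 2
    a, d = divmod(c, 3)
    fd = _fd_second(
        st,
        lambda s, e: s.z[0].__setitem__((0, 0), s.z[0][0, 0] + e),
        lambda s, e: s.nuclear.positions.__setitem__((a, d),
                                                     s.nuclear.positions[a, d] + e),
        eps,
    )
    assert cm.C_R[0, c] == pytest.approx(fd, rel=2e-6, abs=2e-6)

    # C_XY nuclear block: -2 Im d2 lnS / dR'_1 dR''_5
    c1, c2 = 1, 5
    a1, d1 = divmod(c1, 3)
    a2, d2 = divmod(c2, 3)
    fd = _fd_second(
        st,
        lambda s, e: s.nuclear.positions.__setitem__((a1, d1),
                                                     s.nuclear.positions[a1, d1] + e),
        lambda s, e: s.nuclear.positions.__setitem__((a2, d2),
                                                     s.nuclear.positions[a2, d2] + e),
        eps,
    )
    assert cm.C_XY[c1, c2] == pytest.approx(
        -2.0 * np.imag(fd), rel=2e-5, abs=2e-6
    )


def test_travelling_couplings_match_lnS_finite_differences(h2p_det):
    """Momentum-derivative blocks (travelling basis) against ln S
    finite differences."""
    st = _random_state(h2p_det, seed=8, mode="travelling")
    ws = EOMWorkspace(st)
    cm = ws.coupling_matrices()
    eps = 1e-4
    c = 4
    a, d = divmod(c, 3)
    fd = _fd_second(
        st,
        lambda s, e: s.z[0].__setitem__((0, 0), s.z[0][0, 0] + e),
        lambda s, e: s.nuclear.momenta.__setitem__((a, d),
                                                   s.nuclear.momenta[a, d] + e),
        eps,
    )
    assert cm.C_P[0, c] == pytest.approx(fd, rel=5e-3, abs=1e-9)


def test_travelling_momentum_gradient_matches_fd(h2p_det):
    st = _random_state(h2p_det, seed=9, mode="travelling")
    g = energy_gradients(st)
    eps = 1e-4
    fd = np.zeros(6)
    for c in range(6):
        a, d = divmod(c, 3)
        sp = st.copy()
        sp.nuclear.momenta[a, d] += eps
        sm = st.copy()
        sm.nuclear.momenta[a, d] -= eps
        fd[c] = (total_energy(sp) - total_energy(sm)) / (2 * eps)
    assert np.abs(g.dE_dP - fd).max() < 1e-9
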