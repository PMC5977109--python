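"""Fragment identification, channel labels, charge series, transfer
probabilities, cross sections and the cluster scaling fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slend.analysis import (
    BOND_SCALE,
    COVALENT_RADII,
    TransferProbabilityCurve,
    charge_series,
    classify_channel,
    compare_to_reference,
    cross_section,
    fit_scaling,
    identify_fragments,
    transfer_probability,
)
from slend.chem_system import build_fixture
from slend.thouless_dynamics.state import Frame, Trajectory


# ---- fragments ------------------------------------------------------

def test_h_far_from_oh_gives_two_fragments():
    pos = np.array([[0, 0, 0], [0, 0, 1.8], [0, 0, 11.8]])
    fa = identify_fragments(pos, [8, 1, 1])
    assert fa.n_fragments == 2
    assert sorted(fa.formulas) == ["H", "OH"]


def test_equilibrium_water_single_fragment(h2o):
    fa = identify_fragments(h2o.positions, [int(z) for z in h2o.charges])
    assert fa.n_fragments == 1
    assert fa.formulas == ["H2O"]


def test_water_cluster_is_n_waters():
    cl = build_fixture("water_cluster_n4_s4")
    fa = identify_fragments(cl.positions, [int(z) for z in cl.charges])
    assert fa.n_fragments == 4
    assert fa.formulas == ["H2O"] * 4


def test_threshold_boundary_is_bonded_vs_pairwise_oracle():
    """O-H exactly at the cutoff distance counts as bonded (closed
    boundary), matching a brute-force pairwise check."""
    cut = BOND_SCALE * (COVALENT_RADII[8] + COVALENT_RADII[1])
    pos = np.array([[0, 0, 0], [0, 0, cut]])
    fa = identify_fragments(pos, [8, 1])
    bonded_oracle = np.linalg.norm(pos[0] - pos[1]) <= cut
    assert (fa.n_fragments == 1) == bonded_oracle
    pos2 = np.array([[0, 0, 0], [0, 0, cut * (1 + 1e-9)]])
    assert identify_fragments(pos2, [8, 1]).n_fragments == 2


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_channel_label_invariant_under_permutation_and_rotation(seed):
    rng = np.random.default_rng(seed)
    cl = build_fixture("water_cluster_n3")
    pos = cl.positions
    zs = [int(z) for z in cl.charges]
    # random rigid rotation + permutation
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    perm = rng.permutation(len(zs))
    lab0 = classify_channel(identify_fragments(pos, zs))
    lab1 = classify_channel(
        identify_fragments((pos @ R.T)[perm], [zs[i] for i in perm])
    )
    assert lab0 == lab1


def test_channel_labels_of_radiolysis_products():
    # H + OH + 3 H2O (the monomer-splitting channel of a tetramer run)
    waters = build_fixture("water_cluster_n3")
    pos = list(waters.positions)
    zs = [int(z) for z in waters.charges]
    pos += [[30, 0, 0], [40, 0, 0], [40, 0, 1.8], [-30, 0, 0]]
    zs += [1, 8, 1, 1]
    fa = identify_fragments(np.array(pos), zs)
    lab = classify_channel(fa, projectile_index=len(zs) - 1)
    assert lab.label == "H + 3 H2O + OH (+H proj)"


def _toy_trajectory(mulliken_frames, positions, charges, masses, ref=None):
    traj = Trajectory(reference=ref, etf_mode="static",
                      meta={"masses": np.asarray(masses, float),
                            "charges": np.asarray(charges, float)})
    for k, (q, pos) in enumerate(zip(mulliken_frames, positions)):
        traj.add(Frame(
            time=float(k), positions=np.asarray(pos, float),
            momenta=np.zeros_like(np.asarray(pos, float)),
            z=[np.zeros((0, 0)), np.zeros((0, 0))],
            energy=0.0, mulliken=np.asarray(q, float), z_norm=0.0,
            step_size=1.0, rcond=1.0,
        ))
    return traj


# ---- charge series --------------------------------------------------

def test_charge_series_single_group_is_total_charge():
    q = [[-0.2, -0.8], [-0.5, -0.5], [-0.9, -0.1]]
    pos = [np.zeros((2, 3))] * 3
    traj = _toy_trajectory(q, pos, [1, 1], [1836.0, 1836.0])
    t, series = charge_series(traj, [[0, 1]])
    assert np.allclose(series[:, 0], -1.0)


def test_charge_series_additivity_and_partition_check():
    q = [[0.1, 0.4, -0.5], [0.2, 0.2, -0.4]]
    pos = [np.zeros((3, 3))] * 2
    traj = _toy_trajectory(q, pos, [1, 1, 8], [1.0, 1.0, 16.0])
    _, two = charge_series(traj, [[0, 1], [2]])
    _, one = charge_series(traj, [[0, 1, 2]])
    assert np.allclose(two.sum(axis=1), one[:, 0])
    with pytest.raises(ValueError):
        charge_series(traj, [[0, 1]])  # atom 2 missing


# ---- transfer probability ------------------------------------------

class _FakeRef:
    n_electrons = 2


def test_transfer_probability_constructed_final_states():
    pos = [np.array([[0, 0, 0.0], [0, 0, 1.4], [40.0, 0, 0]])] * 2
    # one full electron on the projectile: q_proj = 0 for an H+ start
    q_full = [[0.5, 0.5, 0.0]] * 2
    traj = _toy_trajectory(q_full, pos, [1, 1, 1],
                           [1836.0, 1836.0, 1836.0], ref=_FakeRef())
    out = transfer_probability(traj, projectile_index=2)
    assert out["P"] == pytest.approx(1.0, abs=1e-12)
    # untouched projectile charge +1 -> no transfer
    q_none = [[0.0, 0.0, 1.0]] * 2
    traj = _toy_trajectory(q_none, pos, [1, 1, 1],
                           [1836.0, 1836.0, 1836.0], ref=_FakeRef())
    assert transfer_probability(traj, 2)["P"] < 1e-6


def test_transfer_probability_requires_separation():
    pos = [np.array([[0, 0, 0.0], [0, 0, 1.4], [5.0, 0, 0]])]
    traj = _toy_trajectory([[0.0, 0.0, 1.0]], pos, [1, 1, 1],
                           [1836.0] * 3, ref=_FakeRef())
    with pytest.raises(ValueError, match="not separated"):
        transfer_probability(traj, 2)


def test_resonant_two_level_charge_oscillation(h2p_det):
    """Electron initially localized on one proton of a stretched H2+
    oscillates with the g/u Rabi period; the Mulliken population matches
    the exact two-state evolution to 0.01."""
    from slend.chem_system import Atom, MolecularSystem
    from slend.electronic_structure.integrals import compute_integrals
    from slend.electronic_structure.scf import run_uhf
    from slend.thouless_dynamics import (
        NuclearConfiguration,
        PropagationControls,
        ThoulessState,
        propagate,
    )

    sys = MolecularSystem(
        [Atom("H", [0, 0, 0]), Atom("H", [0, 0, 6.0])], 1, 2, "h2p_far"
    )
    det = run_uhf(sys, "sto-3g")
    ints = compute_integrals(det.basis, need_eri=False)
    h_mo = det.C[0].T @ ints.hcore @ det.C[0]
    d_eps = h_mo[1, 1] - h_mo[0, 0]
    # z=1: chi = g + u, localized on atom A (up to the tiny overlap)
    nuc = NuclearConfiguration(
        sys.positions, np.zeros((2, 3)), [1e10, 1e10], sys.charges
    )
    st = ThoulessState(det, nuc, [np.array([[1.0 + 0j]]), np.zeros((2, 0))])
    T = 0.5 * np.pi / abs(d_eps)  # quarter Rabi period: P_B = 0.5
    traj = propagate(st, T, PropagationControls(rtol=1e-10, atol=1e-12,
                                                record_every=100))
    pop_b = 1.0 - traj.frames[-1].mulliken[1]  # Z_B - q_B
    exact = np.sin(abs(d_eps) * T / 2.0) ** 2
    assert pop_b == pytest.approx(exact, abs=0.01)


# ---- cross sections -------------------------------------------------

def test_gaussian_profile_integrates_to_pi():
    b = np.linspace(0, 6, 2001)
    curve = TransferProbabilityCurve(
        b, np.exp(-b * b), np.zeros_like(b), np.ones_like(b, int)
    )
    xs = cross_section(curve)
    assert xs.sigma == pytest.approx(np.pi, rel=1e-4)


def test_zero_profile_gives_zero():
    b = np.linspace(0, 3, 10)
    curve = TransferProbabilityCurve(
        b, np.zeros_like(b), np.zeros_like(b), np.ones_like(b, int)
    )
    assert cross_section(curve).sigma == 0.0


def test_step_profile_gives_geometric_area():
    b0 = 2.0
    b = np.linspace(0, 4, 8001)
    P = (b < b0).astype(float)
    curve = TransferProbabilityCurve(b, P, np.zeros_like(b),
                                     np.ones_like(b, int))
    xs = cross_section(curve)
    assert xs.sigma == pytest.approx(np.pi * b0 * b0, rel=1e-3)


def test_grid_refinement_changes_less_than_reported_error():
    rng = np.random.default_rng(0)
    f = lambda b: np.exp(-0.7 * b**2) * (1 + 0.2 * np.sin(b))
    b1 = np.linspace(0, 6, 41)
    b2 = np.linspace(0, 6, 81)
    xs1 = cross_section(TransferProbabilityCurve(
        b1, f(b1), np.zeros_like(b1), np.ones_like(b1, int)))
    xs2 = cross_section(TransferProbabilityCurve(
        b2, f(b2), np.zeros_like(b2), np.ones_like(b2, int)))
    assert abs(xs2.sigma - xs1.sigma) < max(xs1.quad_error, 1e-12) * 2


def test_cross_section_guards():
    with pytest.raises(ValueError, match="extend the grid"):
        b = np.linspace(0, 2, 10)
        cross_section(TransferProbabilityCurve(
            b, np.full_like(b, 0.5), np.zeros_like(b),
            np.ones_like(b, int)))
    with pytest.raises(ValueError, match="insufficient grid"):
        cross_section(TransferProbabilityCurve(
            np.array([1.0]), np.array([0.0]), np.array([0.0]),
            np.array([1])))


# ---- scaling fit ----------------------------------------------------

def test_exact_power_law_recovered():
    pts = [(n, 2.0 * n ** (2 / 3)) for n in range(1, 7)]
    fit = fit_scaling(pts)
    assert fit.c == pytest.approx(2.0, rel=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_single_point_fit():
    fit = fit_scaling([(1, 1.54)])
    assert fit.c == pytest.approx(1.54, rel=1e-12)


def test_noisy_fit_matches_nonlinear_least_squares_oracle():
    from scipy.optimize import curve_fit

    rng = np.random.default_rng(11)
    n = np.arange(1, 7, dtype=float)
    sig = 1.3 * n ** (2 / 3) + 0.05 * rng.standard_normal(6)
    fit = fit_scaling(list(zip(n, sig)))
    popt, _ = curve_fit(lambda x, c: c * x ** (2 / 3), n, sig, p0=[1.0])
    assert fit.c == pytest.approx(float(popt[0]), abs=1e-8)


def test_fit_scale_equivariance():
    rng = np.random.default_rng(2)
    pts = [(n, float(rng.uniform(1, 3))) for n in range(1, 7)]
    f1 = fit_scaling(pts)
    f2 = fit_scaling([(n, 5.0 * s) for n, s in pts])
    assert f2.c == pytest.approx(5.0 * f1.c, rel=1e-12)
    assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-12)


def test_fit_guards():
    with pytest.raises(ValueError):
        fit_scaling([])
    with pytest.raises(ValueError):
        fit_scaling([(0.5, 1.0)])


# ---- reference comparisons -----------------------------------------

def test_compare_to_reference_cytosine_cdw():
    """1.9 vs 2.3 (1e-19 m^2) is a -17.4% deviation."""
    from slend.analysis import CrossSection

    xs = CrossSection(
        sigma=1.9 / 0.1 / CrossSection.BOHR2_TO_ANG2,  # 1.9e-19 m^2 in Bohr^2
        quadrature="trapezoid", stat_error=0.0, quad_error=0.0,
    )
    rep = compare_to_reference(xs, "cytosine_80kev_expt")
    assert rep["deviation_percent"] == pytest.approx(-17.39, abs=0.01)
    assert rep["within_error"] is True  # 1.9 > 2.3 - 0.5


def test_compare_identical_value_is_zero_percent():
    from slend.analysis import CrossSection

    xs = CrossSection(
        sigma=1.54 / CrossSection.BOHR2_TO_ANG2,
        quadrature="trapezoid", stat_error=0.0, quad_error=0.0,
    )
    rep = compare_to_reference(xs, "h2o_100kev_slend_631gs")
    assert rep["deviation_percent"] == pytest.approx(0.0, abs=1e-10)


def test_compare_missing_key():
    from slend.analysis import CrossSection

    xs = CrossSection(1.0, "trapezoid", 0.0, 0.0)
    with pytest.raises(KeyError):
        compare_to_reference(xs, "nope")
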