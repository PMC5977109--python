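"""Collision/attachment preparation, orientation sampling, scenarios."""

import numpy as np
import pytest

from slend.chem_system import PROTON_MASS_AU, build_fixture
from slend.scattering import (
    AttachmentSpec,
    CollisionSpec,
    StoppingRule,
    prepare_attachment,
    prepare_collision,
    run_scenario,
    sample_orientations,
)
from slend.thouless_dynamics import PropagationControls, state_mulliken


# ---- collisions -----------------------------------------------------

def test_prepared_collision_momentum_and_geometry(h2):
    spec = CollisionSpec(
        target=h2, energy_kev=100.0, impact_parameter=1.5,
        basis="sto-3g", etf_mode="static",
    )
    st = prepare_collision(spec)
    p = st.nuclear.momenta[-1]
    assert np.linalg.norm(p) == pytest.approx(3673.7, abs=0.5)
    assert p[1] == 0.0 and p[2] == 0.0  # beam along +x
    r = st.nuclear.positions[-1]
    assert r[0] == pytest.approx(-30.0) and r[1] == pytest.approx(1.5)


def test_prepared_collision_b0_is_collinear_with_aim(h2o):
    spec = CollisionSpec(
        target=h2o, energy_kev=1.0, impact_parameter=0.0,
        basis="sto-3g", aim=0,  # aim at the O atom
    )
    st = prepare_collision(spec)
    # the beam line (+x through the projectile start) passes through the
    # aim atom, which the preparation moved to the origin
    assert np.abs(st.nuclear.positions[0]).max() < 1e-12
    assert abs(st.nuclear.positions[-1][1]) < 1e-12


def test_prepared_collision_population_stays_on_target(h2o):
    spec = CollisionSpec(
        target=h2o, energy_kev=1.0, impact_parameter=1.0, basis="sto-3g"
    )
    st = prepare_collision(spec)
    q = state_mulliken(st)
    assert q[-1] == pytest.approx(1.0, abs=1e-6)  # bare proton
    assert q.sum() == pytest.approx(1.0, abs=1e-8)


def test_collision_separation_too_small_rejected(h2):
    spec = CollisionSpec(
        target=h2, energy_kev=1.0, impact_parameter=0.5,
        basis="sto-3g", separation=5.0,
    )
    with pytest.raises(ValueError, match="separation too small"):
        prepare_collision(spec)


def test_etf_mode_auto_rule(h2):
    low = CollisionSpec(target=h2, energy_kev=1.0, impact_parameter=0.0)
    high = CollisionSpec(target=h2, energy_kev=80.0, impact_parameter=0.0)
    assert low.resolved_mode() == "static"
    assert high.resolved_mode() == "travelling"


# ---- orientations ---------------------------------------------------

def test_orientations_deterministic_from_seed():
    a = sample_orientations(5, seed=42)
    b = sample_orientations(5, seed=42)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra, rb)
    c = sample_orientations(5, seed=43)
    assert not np.array_equal(a[0], c[0])


def test_orientations_are_proper_rotations():
    for r in sample_orientations(20, seed=1):
        assert np.abs(r @ r.T - np.eye(3)).max() < 1e-12
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)


def test_orientation_average_matches_analytic_mean():
    """E[(R v).u] over uniform rotations is 0 for any fixed u, v; the
    Monte-Carlo mean must land within 3 standard errors."""
    rots = sample_orientations(10_000, seed=7)
    v = np.array([1.0, 0.0, 0.0])
    u = np.array([0.3, -0.5, 0.8])
    vals = np.array([(r @ v) @ u for r in rots])
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se


# ---- attachment -----------------------------------------------------

def test_attachment_bookkeeping_h2o(h2o):
    st = prepare_attachment(
        AttachmentSpec(host=h2o, virtual_offset=0, spin="alpha")
    )
    sys = st.basis.system
    assert sys.charge == -1
    assert st.reference.n_electrons == 11
    assert st.reference.n_occ == (6, 5)  # alpha incremented
    q = state_mulliken(st)
    assert q.sum() == pytest.approx(-1.0, abs=1e-10)
    assert np.abs(st.nuclear.momenta).max() == 0.0


def test_attachment_beta_channel_relabels_majority_spin(h2o):
    st = prepare_attachment(
        AttachmentSpec(host=h2o, virtual_offset=1, spin="beta")
    )
    assert st.reference.n_occ == (6, 5)  # relabeled so alpha is majority


def test_attachment_selector_out_of_range(h2):
    with pytest.raises(IndexError):
        prepare_attachment(AttachmentSpec(host=h2, virtual_offset=5))


def test_attached_orbital_population_is_localized_orbital(h2o):
    """The inserted electron's population difference against the neutral
    host equals the Mulliken profile of the selected virtual."""
    from slend.electronic_structure.integrals import compute_integrals
    from slend.electronic_structure.scf import mulliken_charges, run_uhf

    det = run_uhf(h2o, "sto-3g")
    st = prepare_attachment(AttachmentSpec(host=h2o, virtual_offset=0))
    ints = compute_integrals(det.basis, mode="static", need_eri=False)
    q_neutral = mulliken_charges(
        [det.density(0), det.density(1)], ints.S, det.basis.ao_atom,
        h2o.charges,
    )
    q_anion = state_mulliken(st)
    lumo = det.C[0][:, det.n_occ[0]]
    pop = np.zeros(3)
    for mu, a in enumerate(det.basis.ao_atom):
        pop[a] += (lumo * (ints.S @ lumo))[mu]
    assert np.abs((q_neutral - q_anion) - pop).max() < 1e-8


# ---- scenario driving ----------------------------------------------

def test_run_scenario_max_time(h2_det):
    from conftest import zero_state

    st = zero_state(h2_det)
    traj = run_scenario(
        st, StoppingRule(max_time=10.0),
        PropagationControls(record_every=1),
    )
    assert traj.end_reason == "max_time"
    assert traj.frames[-1].time == pytest.approx(10.0)


def test_run_scenario_separation_rule(h2):
    spec = CollisionSpec(
        target=h2, energy_kev=1.0, impact_parameter=6.0, basis="sto-3g"
    )
    st = prepare_collision(spec)
    traj = run_scenario(
        st,
        StoppingRule(max_time=2000.0, projectile_separation=40.0),
        PropagationControls(record_every=5, max_step=10.0),
        projectile_index=2,
    )
    assert traj.end_reason == "separation"
    # ballistic exit bound: v = 0.2 a.u. over ~70 Bohr of path
    assert traj.frames[-1].time < 600.0


def test_stopping_rule_requires_one_active():
    with pytest.raises(ValueError):
        StoppingRule()
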