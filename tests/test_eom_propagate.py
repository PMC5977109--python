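"""Dynamical equations and propagation: exact limits, conservation,
reversibility, restartability."""

import numpy as np
import pytest
from scipy.linalg import expm

from slend.chem_system import Atom, MolecularSystem, PROTON_MASS_AU
from slend.electronic_structure.integrals import compute_integrals
from slend.electronic_structure.scf import run_uhf
from slend.thouless_dynamics import (
    EOMWorkspace,
    NuclearConfiguration,
    PropagationControls,
    ThoulessState,
    nuclear_from_system,
    propagate,
    reanchor,
    solve_eom,
    state_mulliken,
    total_energy,
)

from conftest import zero_state


def test_scf_stationary_point_has_zero_velocities(h2_equilibrium_det):
    """At the SCF minimum with z = 0, P = 0 every time derivative
    vanishes (equilibrium of the variational dynamics)."""
    st = zero_state(h2_equilibrium_det)
    dz, dR, dP, info = solve_eom(st)
    assert max(np.abs(d).max() if d.size else 0.0 for d in dz) < 1e-8
    assert np.abs(dR).max() < 1e-12
    assert np.abs(dP).max() < 1e-6  # residual force at the scanned minimum
    assert info["rcond"] > 1e-6


def test_bare_proton_eom_is_classical():
    prot = MolecularSystem(
        [Atom("H", [0, 0, 0], mass=PROTON_MASS_AU)], 1, 1
    )
    det = run_uhf(prot, "sto-3g")
    nuc = NuclearConfiguration(
        [[0, 0, 0]], [[3.0, -1.0, 0.5]], [PROTON_MASS_AU], [1.0]
    )
    st = ThoulessState(det, nuc, [np.zeros((1, 0)), np.zeros((1, 0))])
    dz, dR, dP, _ = solve_eom(st)
    assert all(d.size == 0 for d in dz)
    assert np.allclose(dR, nuc.momenta.ravel() / PROTON_MASS_AU, atol=1e-14)
    assert np.abs(dP).max() < 1e-14


def test_solve_matches_dense_linear_algebra_oracle(h2p_det):
    """The factorized Pfaffian solve equals an independent dense solve
    of the same assembled system."""
    rng = np.random.default_rng(12)
    st = zero_state(h2p_det)
    st.z[0][:] = 0.2 * rng.standard_normal((1, 1)) + 0.1j
    st.nuclear.momenta[:] = rng.standard_normal((2, 3))
    dz, dR, dP, _ = solve_eom(st)
    ws = EOMWorkspace(st)
    ydot = np.linalg.lstsq(ws.omega(), ws.rhs(), rcond=None)[0]
    nz = st.z[0].size
    got = np.concatenate(
        [dz[0].ravel().real, dz[0].ravel().imag, dR, dP]
    )
    ref = np.concatenate(
        [ydot[:nz], ydot[nz: 2 * nz], ydot[2 * nz: 2 * nz + 6],
         ydot[2 * nz + 6:]]
    )
    assert np.abs(got - ref).max() < 1e-10


def test_free_projectile_is_ballistic():
    prot = MolecularSystem(
        [Atom("H", [0, 0, 0], mass=PROTON_MASS_AU)], 1, 1
    )
    det = run_uhf(prot, "sto-3g")
    p0 = np.array([2.0, 0.3, -0.1]) * PROTON_MASS_AU
    nuc = NuclearConfiguration([[0, 0, 0]], [p0], [PROTON_MASS_AU], [1.0])
    st = ThoulessState(det, nuc, [np.zeros((1, 0)), np.zeros((1, 0))])
    traj = propagate(
        st, 1000.0, PropagationControls(max_step=100.0, record_every=50)
    )
    expect = p0 / PROTON_MASS_AU * 1000.0
    assert np.abs(traj.frames[-1].positions[0] - expect).max() < 1e-8
    assert np.abs(traj.frames[-1].momenta[0] - p0).max() < 1e-12


def test_scf_ground_state_stays_stationary(h2_equilibrium_det):
    """z stays below 1e-8 and the nuclei below 1e-8 Bohr over 10 a.u.
    at the scanned SCF minimum."""
    st = zero_state(h2_equilibrium_det)
    traj = propagate(st, 10.0, PropagationControls(record_every=1))
    assert traj.frames[-1].z_norm < 1e-8
    disp = np.abs(
        traj.frames[-1].positions - traj.frames[0].positions
    ).max()
    assert disp < 1e-8


def test_frozen_nuclei_matches_two_level_unitary(h2p_det):
    """With effectively frozen nuclei, the one-electron K=2 propagation
    equals exact 2x2 unitary evolution under the one-electron
    Hamiltonian fixed at t=0 (masses chosen so residual nuclear motion
    lies below the tolerance)."""
    det = h2p_det
    ints = compute_integrals(det.basis, need_eri=False)
    h_mo = det.C[0].T @ ints.hcore @ det.C[0]
    z0 = 0.35 + 0.2j
    sys = det.basis.system
    nuc = NuclearConfiguration(
        sys.positions, np.zeros((2, 3)), [1e10, 1e10], sys.charges
    )
    st = ThoulessState(det, nuc, [np.array([[z0]]), np.zeros((2, 0))])
    T = 100.0
    traj = propagate(
        st, T, PropagationControls(rtol=1e-11, atol=1e-13, record_every=500)
    )
    ct = expm(-1j * h_mo * T) @ np.array([1.0, z0])
    z_exact = ct[1] / ct[0]
    assert abs(traj.frames[-1].z[0][0, 0] - z_exact) < 1e-6


def test_energy_conservation_and_tolerance_scaling(h2_det):
    """Vibrating H2: relative drift below 1e-6 per 1000 a.u. at default
    tolerances; tightening rtol by 10x cuts the drift by >= 5x."""
    st = zero_state(h2_det)  # 1.4 Bohr is off-minimum: it vibrates

    def drift(rtol):
        traj = propagate(
            st, 400.0,
            PropagationControls(rtol=rtol, atol=rtol * 1e-2,
                                record_every=10),
        )
        e = traj.energies
        return np.abs(e - e[0]).max()

    d_default = drift(1e-7)
    assert d_default / abs(h2_det.energy) < 1e-6 * 0.4  # per 400 a.u.
    d_loose = drift(1e-4)
    d_tight = drift(1e-5)
    assert d_tight <= d_loose / 5.0


def test_charge_sum_constant_along_trajectory(h2_det):
    st = zero_state(h2_det)
    st.nuclear.momenta[0, 2] = 1.5  # kick one atom
    traj = propagate(st, 60.0, PropagationControls(record_every=2))
    sums = traj.mulliken.sum(axis=1)
    assert np.abs(sums - 0.0).max() < 1e-8


def test_time_reversal_recovers_initial_state(h2p_det):
    rng = np.random.default_rng(3)
    st0 = ThoulessState(
        h2p_det,
        NuclearConfiguration(
            h2p_det.basis.system.positions,
            rng.standard_normal((2, 3)) * 2.0,
            h2p_det.basis.system.masses,
            h2p_det.basis.system.charges,
        ),
        [0.2 * rng.standard_normal((1, 1)) + 0.1j * rng.standard_normal((1, 1)),
         np.zeros((2, 0))],
    )
    ctl = PropagationControls(rtol=1e-10, atol=1e-12)
    fwd = propagate(st0, 20.0, ctl)
    end = fwd.final_state()
    rev = propagate(end.time_reversed(), end.time + 20.0, ctl)
    back = rev.final_state().time_reversed()
    assert np.abs(back.nuclear.positions - st0.nuclear.positions).max() < 1e-5
    assert np.abs(back.nuclear.momenta - st0.nuclear.momenta).max() < 1e-5
    assert abs(back.z[0][0, 0] - st0.z[0][0, 0]) < 1e-5


def test_reanchor_preserves_energy_and_charges(h2_det):
    rng = np.random.default_rng(21)
    st = zero_state(h2_det)
    st.z[0][:] = 0.4 * rng.standard_normal((1, 1)) + 0.3j
    st.z[1][:] = 0.2 - 0.1j
    e0 = total_energy(st)
    q0 = state_mulliken(st)
    st2 = reanchor(st)
    assert st2.z_norm() == 0.0
    assert total_energy(st2) == pytest.approx(e0, abs=1e-10)
    assert np.abs(state_mulliken(st2) - q0).max() < 1e-10


def test_trajectory_times_strictly_increase(h2_det):
    st = zero_state(h2_det)
    traj = propagate(st, 5.0, PropagationControls(record_every=1))
    assert np.all(np.diff(traj.times) > 0)
    assert traj.end_reason == "max_time"


def test_in_run_reanchoring_keeps_energy_continuous(h2_det):
    """Starting from a displaced point of the Thouless chart with the
    re-anchor control armed, the propagator refreshes the reference
    mid-run; total energy and charges stay continuous across the event
    and z returns to a small-norm chart."""
    from conftest import zero_state

    st = zero_state(h2_det)
    st.z[0][:] = 0.35 + 0.2j  # displaced chart point (norm > threshold)
    traj = propagate(
        st, 40.0,
        PropagationControls(record_every=1, reanchor_threshold=0.05,
                            energy_tol=1e-2),
    )
    events = traj.meta.get("events", [])
    assert events and all(e["type"] == "reanchor" for e in events)
    e = traj.energies
    assert np.abs(e - e[0]).max() < 1e-5
    assert np.abs(traj.mulliken.sum(axis=1)).max() < 1e-8
    # the refreshed chart keeps z well below the starting displacement
    assert traj.frames[-1].z_norm < 0.4
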