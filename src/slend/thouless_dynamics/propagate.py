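"""Adaptive time integration of the SLEND equations.

An embedded Runge-Kutta 5(4) scheme (scipy's RK45, stepped manually so
every accepted step can be recorded, checkpointed and diagnosed) acts on
the flattened real vector (Re z, Im z, R, P).  Each right-hand-side
evaluation performs one Pfaffian solve.  The total energy is monitored
along the run; drift beyond the requested tolerance raises rather than
silently degrading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import RK45

from .eom import EOMWorkspace, SingularMetricError, solve_eom, state_mulliken
from .state import Frame, ThoulessState, Trajectory


@dataclass
class PropagationControls:
    """Integrator and diagnostic settings.

    rtol/atol are the embedded-RK error tolerances on the flattened state
    vector; energy_tol is the maximum |E(t) - E(0)| allowed before the
    run aborts; record_every records one frame per that many accepted
    steps (the first and last frames are always recorded).
    """

    rtol: float = 1e-7
    atol: float = 1e-9
    max_step: float = 5.0
    first_step: float | None = 0.01
    energy_tol: float = 1e-3
    record_every: int = 1
    max_steps: int = 2_000_000
    stop_condition: object = None  # callable(state) -> str | None
    #: re-express the state over a fresh reference (z -> 0) whenever
    #: ||z|| exceeds this; off by default.  Each event is logged in the
    #: trajectory metadata.
    reanchor_threshold: float | None = None


class StepSizeUnderflow(RuntimeError):
    pass


def _rhs_factory(template: ThoulessState):
    def rhs(t, y):
        state = template.unpack(y, time=t)
        dz, dR, dP, _ = solve_eom(state)
        nz = sum(z.size for z in state.z)
        out = np.empty_like(y)
        off = 0
        re = np.concatenate([d.ravel().real for d in dz])
        im = np.concatenate([d.ravel().imag for d in dz])
        out[:nz] = re
        out[nz: 2 * nz] = im
        out[2 * nz: 2 * nz + dR.size] = dR
        out[2 * nz + dR.size:] = dP
        return out

    return rhs


def _record(traj: Trajectory, state: ThoulessState, step_size: float,
            h_next: float = float("nan")) -> Frame:
    ws = EOMWorkspace(state)
    q = state_mulliken(state, ws)
    frame = Frame(
        time=state.time,
        positions=state.nuclear.positions.copy(),
        momenta=state.nuclear.momenta.copy(),
        z=[z.copy() for z in state.z],
        energy=ws.total_energy(),
        mulliken=q,
        z_norm=state.z_norm(),
        step_size=step_size,
        rcond=np.nan,
        h_next=h_next,
    )
    traj.add(frame)
    return frame


def propagate(
    state: ThoulessState,
    t_end: float,
    controls: PropagationControls | None = None,
) -> Trajectory:
    """Integrate from state.time to t_end, recording a Trajectory.

    Stops early when ``controls.stop_condition`` returns a non-empty
    reason string; otherwise ends with reason 'max_time'.
    """
    controls = controls or PropagationControls()
    if t_end <= state.time:
        raise ValueError("t_end must exceed the state time")
    traj = Trajectory(
        reference=state.reference,
        etf_mode=state.etf_mode,
        meta={
            "masses": state.nuclear.masses.copy(),
            "charges": state.nuclear.charges.copy(),
            "controls": controls,
        },
    )
    def make_solver(from_state, first_step):
        return RK45(
            _rhs_factory(from_state),
            from_state.time,
            from_state.pack(),
            t_end,
            rtol=controls.rtol,
            atol=controls.atol,
            max_step=controls.max_step,
            first_step=first_step,
        )

    solver = make_solver(state, controls.first_step)
    first = _record(traj, state, 0.0, h_next=float(solver.h_abs))
    e0 = first.energy
    n_accept = 0
    reason = ""
    current = state
    template = state
    while solver.status == "running":
        msg = solver.step()
        if solver.status == "failed":
            raise StepSizeUnderflow(
                f"integrator failed at t={solver.t:.4f}: {msg}"
            )
        n_accept += 1
        current = template.unpack(solver.y, time=solver.t)
        record_now = (
            n_accept % max(1, controls.record_every) == 0
            or solver.status == "finished"
        )
        if record_now:
            frame = _record(traj, current, solver.step_size or 0.0,
                            h_next=float(solver.h_abs))
            if abs(frame.energy - e0) > controls.energy_tol:
                traj.end_reason = "energy_drift"
                raise RuntimeError(
                    f"energy drift {frame.energy - e0:+.3e} exceeds "
                    f"tolerance {controls.energy_tol:.1e} at t={solver.t:.3f}"
                )
            if controls.stop_condition is not None:
                r = controls.stop_condition(current)
                if r:
                    reason = r
                    break
            if (
                controls.reanchor_threshold is not None
                and frame.z_norm > controls.reanchor_threshold
                and solver.status == "running"
            ):
                from .eom import reanchor

                current = reanchor(current)
                template = current
                traj.reference = current.reference
                traj.meta.setdefault("events", []).append(
                    {"type": "reanchor", "time": current.time,
                     "z_norm": frame.z_norm}
                )
                solver = make_solver(current, float(solver.h_abs))
        if n_accept >= controls.max_steps:
            reason = "max_steps"
            break
    if not reason:
        reason = "max_time" if solver.status == "finished" else reason
    if traj.frames[-1].time < current.time:
        _record(traj, current, solver.step_size or 0.0,
                h_next=float(solver.h_abs))
    traj.end_reason = reason or "max_time"
    return traj
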