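"""Trajectory sidecar files.

Each trajectory is written as a multi-frame XYZ (geometry, human
readable) plus a self-describing HDF5 sidecar holding the per-frame
numerics: time (a.u. and fs), total energy, Mulliken charges, the
complex Thouless coefficients, step diagnostics and the restart seed.
Checkpoint restart is bit-identical: re-running the integrator from a
stored frame (state + trial step) reproduces the remaining frames.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from ..chem_system.system import MolecularSystem, write_multi_xyz
from ..chem_system.units import AU_TIME_FS
from ..thouless_dynamics.propagate import PropagationControls, propagate
from ..thouless_dynamics.state import (
    NuclearConfiguration,
    ThoulessState,
    Trajectory,
)


def write_sidecar(traj: Trajectory, path: str | Path) -> None:
    frames = traj.frames
    nf = len(frames)
    with h5py.File(path, "w") as f:
        f.attrs["etf_mode"] = traj.etf_mode
        f.attrs["end_reason"] = traj.end_reason
        f.attrs["beam_frame"] = traj.meta.get("beam_frame", "")
        f.attrs["n_frames"] = nf
        times = np.array([fr.time for fr in frames])
        f["time_au"] = times
        f["time_fs"] = times * AU_TIME_FS
        f["energy"] = np.array([fr.energy for fr in frames])
        f["positions"] = np.array([fr.positions for fr in frames])
        f["momenta"] = np.array([fr.momenta for fr in frames])
        f["mulliken"] = np.array([fr.mulliken for fr in frames])
        f["z_norm"] = np.array([fr.z_norm for fr in frames])
        f["step_size"] = np.array([fr.step_size for fr in frames])
        f["h_next"] = np.array([fr.h_next for fr in frames])
        for s in range(2):
            f[f"z{s}"] = np.array([fr.z[s] for fr in frames])
        f["masses"] = traj.meta["masses"]
        f["charges"] = traj.meta["charges"]


def export_text(traj: Trajectory, path: str | Path) -> None:
    """Flat delimited-text export of the per-frame scalars + charges."""
    frames = traj.frames
    natom = frames[0].mulliken.shape[0]
    header = (
        ["time_au", "time_fs", "energy", "z_norm", "step_size"]
        + [f"q_{i}" for i in range(natom)]
    )
    rows = []
    for fr in frames:
        rows.append(
            [fr.time, fr.time * AU_TIME_FS, fr.energy, fr.z_norm,
             fr.step_size]
            + list(fr.mulliken)
        )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def write_trajectory_xyz(
    traj: Trajectory, system: MolecularSystem, path: str | Path
) -> None:
    frames = [
        (fr.time, system.with_positions(fr.positions))
        for fr in traj.frames
    ]
    write_multi_xyz(frames, path)


def load_checkpoint(
    path: str | Path, traj_template: Trajectory, frame_index: int = -1
) -> tuple[ThoulessState, float]:
    """Rebuild (state, trial step) from a sidecar frame."""
    with h5py.File(path, "r") as f:
        t = float(f["time_au"][frame_index])
        pos = np.array(f["positions"][frame_index])
        mom = np.array(f["momenta"][frame_index])
        z = [np.array(f[f"z{s}"][frame_index]) for s in range(2)]
        h_next = float(f["h_next"][frame_index])
        masses = np.array(f["masses"])
        charges = np.array(f["charges"])
        etf_mode = str(f.attrs["etf_mode"])
    nuc = NuclearConfiguration(pos, mom, masses, charges)
    state = ThoulessState(
        traj_template.reference, nuc, z, t, etf_mode
    )
    return state, h_next


def restart(
    path: str | Path,
    traj_template: Trajectory,
    t_end: float,
    controls: PropagationControls,
    frame_index: int = -1,
) -> Trajectory:
    """Continue a run from a sidecar checkpoint frame.

    With ``record_every=1`` and the stored trial step, the continuation
    reproduces the remaining frames of the original run bit-identically
    (the integrator state is fully determined by t, y and the trial
    step).
    """
    state, h_next = load_checkpoint(path, traj_template, frame_index)
    from dataclasses import replace

    controls = replace(controls, first_step=h_next)
    return propagate(state, t_end, controls)
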