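"""Scenario-grid execution and manifests.

Runs the (impact parameter x orientation) grid of a validated config,
writes one trajectory (XYZ + HDF5 sidecar) per grid point with
deterministic names, and emits a JSON manifest binding every output to
its seed, settings and checksum.  All randomness flows from the single
config seed through one seeded generator (orientation sampling).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .. import __version__
from ..analysis import transfer_probability
from ..chem_system.fixtures import build_fixture
from ..scattering import (
    AttachmentSpec,
    CollisionSpec,
    StoppingRule,
    prepare_attachment,
    prepare_collision,
    run_scenario,
    sample_orientations,
)
from ..thouless_dynamics.propagate import PropagationControls
from .config import RunConfig
from .sidecar import export_text, write_sidecar, write_trajectory_xyz


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _controls(cfg: RunConfig) -> PropagationControls:
    d = cfg.dynamics
    return PropagationControls(
        rtol=d.rtol,
        atol=d.atol,
        max_step=d.max_step,
        energy_tol=d.energy_tol,
        record_every=d.record_every,
    )


def _stopping(cfg: RunConfig) -> StoppingRule:
    s = cfg.dynamics.stopping
    if (
        s.max_time is None
        and s.projectile_separation is None
        and s.fragment_separation is None
    ):
        return StoppingRule(max_time=500.0)
    return StoppingRule(
        max_time=s.max_time,
        projectile_separation=s.projectile_separation,
        fragment_separation=s.fragment_separation,
    )


def run_config(cfg: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute a config; returns the manifest path."""
    outdir = Path(outdir or cfg.output.directory)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = cfg.scenario
    system = build_fixture(scenario.system)
    controls = _controls(cfg)
    stopping = _stopping(cfg)
    records = []
    failures = 0

    if scenario.kind == "collision":
        orients = sample_orientations(scenario.orientations, scenario.seed)
        grid = [
            (b, io) for b in scenario.b_list
            for io in range(len(orients))
        ]
        for b, io in grid:
            tag = f"b{b:07.3f}_o{io:03d}"
            spec = CollisionSpec(
                target=system,
                energy_kev=scenario.energy_kev,
                impact_parameter=b,
                basis=scenario.basis,
                separation=scenario.separation,
                orientation=orients[io],
                aim=scenario.aim,
                etf_mode=cfg.dynamics.etf_mode,
            )
            state = prepare_collision(spec)
            proj_idx = state.nuclear.n_atoms - 1
            record = {
                "tag": tag,
                "b": b,
                "orientation_index": io,
                "seed": scenario.seed,
                "energy_kev": scenario.energy_kev,
                "basis": scenario.basis,
                "etf_mode": state.etf_mode,
                "system": scenario.system,
                "n_waters": _count_waters(system),
            }
            try:
                traj = run_scenario(
                    state, stopping, controls, projectile_index=proj_idx
                )
                record["end_reason"] = traj.end_reason
                try:
                    tp = transfer_probability(traj, proj_idx)
                    record["transfer_probability"] = tp["P"]
                    record["contaminated"] = tp["contaminated"]
                except ValueError as exc:
                    record["transfer_probability"] = None
                    record["transfer_error"] = str(exc)
                record["files"] = _write_outputs(
                    traj, state, outdir, tag, cfg
                )
            except Exception as exc:  # recorded, reported via exit code
                record["end_reason"] = "error"
                record["error"] = str(exc)
                failures += 1
            records.append(record)
    else:
        spec = AttachmentSpec(
            host=system,
            virtual_offset=scenario.virtual_offset,
            spin=scenario.spin,
            basis=scenario.basis,
        )
        state = prepare_attachment(spec)
        record = {
            "tag": "attachment",
            "seed": scenario.seed,
            "basis": scenario.basis,
            "etf_mode": state.etf_mode,
            "system": scenario.system,
            "virtual_offset": scenario.virtual_offset,
            "spin": scenario.spin,
        }
        try:
            traj = run_scenario(state, stopping, controls)
            record["end_reason"] = traj.end_reason
            record["files"] = _write_outputs(
                traj, state, outdir, "attachment", cfg
            )
        except Exception as exc:
            record["end_reason"] = "error"
            record["error"] = str(exc)
            failures += 1
        records.append(record)

    manifest = {
        "package_version": __version__,
        "config": cfg.model_dump(),
        "records": records,
        "failures": failures,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath


def _count_waters(system) -> int | None:
    zs = sorted(int(a.z) for a in system.atoms)
    n_o = zs.count(8)
    if n_o and zs == sorted([8] * n_o + [1] * (2 * n_o)):
        return n_o
    return None


def _write_outputs(traj, state, outdir: Path, tag: str, cfg: RunConfig
                   ) -> dict:
    files = {}
    sc = outdir / f"{tag}.h5"
    write_sidecar(traj, sc)
    files["sidecar"] = sc.name
    xyz = outdir / f"{tag}.xyz"
    write_trajectory_xyz(traj, state.basis.system, xyz)
    files["xyz"] = xyz.name
    if cfg.output.text_export:
        txt = outdir / f"{tag}.tsv"
        export_text(traj, txt)
        files["text"] = txt.name
    for k, name in list(files.items()):
        files[k] = {"name": name, "sha256": _sha256(outdir / name)}
    return files


# ---- cross-section aggregation over manifests ----------------------

def aggregate_xsec(manifest_paths, force: bool = False) -> dict:
    """Aggregate transfer probabilities into P(b) curves and sigma.

    Groups manifests by (system, energy, basis, etf_mode); raises on
    mixed incompatible settings unless ``force``.  Emits the n^(2/3)
    scaling fit whenever several water-cluster sizes are present.
    Aggregation is independent of manifest ordering.
    """
    from ..analysis import (
        TransferProbabilityCurve,
        cross_section,
        fit_scaling,
    )

    records = []
    for path in sorted(str(p) for p in manifest_paths):
        data = json.loads(Path(path).read_text())
        for rec in data["records"]:
            if rec.get("transfer_probability") is None:
                continue
            records.append(rec)
    if not records:
        raise ValueError("no completed transfer-probability records")
    keys = {
        (r["system"], r["energy_kev"], r["basis"], r["etf_mode"])
        for r in records
    }
    settings = {(r["basis"], r["etf_mode"]) for r in records}
    if len(settings) > 1 and not force:
        raise ValueError(
            f"mixed incompatible settings {settings}; pass force=True "
            "to aggregate anyway"
        )
    out = {"groups": []}
    scaling_pts = []
    for key in sorted(keys):
        group = [r for r in records if (
            r["system"], r["energy_kev"], r["basis"], r["etf_mode"]) == key]
        bs = sorted({r["b"] for r in group})
        P, err, cnt = [], [], []
        for b in bs:
            vals = np.array(
                [r["transfer_probability"] for r in group if r["b"] == b]
            )
            P.append(vals.mean())
            err.append(
                vals.std(ddof=1) / np.sqrt(len(vals))
                if len(vals) > 1 else 0.0
            )
            cnt.append(len(vals))
        curve = TransferProbabilityCurve(
            np.array(bs), np.array(P), np.array(err), np.array(cnt)
        )
        xs = cross_section(
            curve,
            provenance={
                "system": key[0], "energy_kev": key[1],
                "basis": key[2], "etf_mode": key[3],
            },
        )
        entry = {
            "system": key[0],
            "energy_kev": key[1],
            "basis": key[2],
            "etf_mode": key[3],
            "b": bs,
            "P": P,
            "stderr": err,
            "sigma_bohr2": xs.sigma,
            "sigma_ang2": xs.sigma_ang2,
            "stat_error_bohr2": xs.stat_error,
            "quad_error_bohr2": xs.quad_error,
        }
        out["groups"].append(entry)
        n = next(
            (r.get("n_waters") for r in group if r.get("n_waters")), None
        )
        if n:
            scaling_pts.append((n, xs.sigma_ang2))
    if len({n for n, _ in scaling_pts}) > 1:
        fit = fit_scaling(scaling_pts)
        out["scaling_fit"] = {
            "c_ang2": fit.c,
            "r_squared": fit.r_squared,
            "points": scaling_pts,
        }
    return out
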