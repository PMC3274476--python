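"""Reproducible pipeline: configuration, stage order, artifacts.

One flat YAML config drives everything. Stages run in fixed order —
simulate (or load stacks), destripe, fuse, drift-correct, detect, track
— and each writes its outputs plus a log entry with parameters and
timing into a JSON run manifest. The whole run is a pure function of
(config, seed): repeated runs produce identical CSV/JSON artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import destripe as _destripe
from . import detect as _detect
from . import dynamics as _dynamics
from . import register as _register
from . import synthetic as _synthetic
from .volume import ImageVolume, read_stack, write_stack

_ALLOWED = {
    "": {"seed", "output_dir", "inputs", "voxel_size_um", "frame_interval_min",
         "simulate", "destripe", "fuse", "driftcorrect", "detect", "track"},
    "simulate": {"enabled", "n_frames", "paclitaxel_mode", "drift_per_frame_um",
                 "division_events", "mitosis_duration_min", "spheroid_radius_um",
                 "n_nuclei", "volume_shape_vox", "labeled_fraction",
                 "mitotic_fraction", "rim_thickness_um", "noise_density",
                 "noise_sd", "attenuation_length_um", "save_stacks"},
    "destripe": {"enabled", "sigma_along_um", "sigma_across_um", "alpha", "prior",
                 "max_iter", "tol"},
    "fuse": {"enabled", "view180", "weights"},
    "driftcorrect": {"enabled", "reference"},
    "detect": {"enabled", "min_radius_um", "max_radius_um", "threshold_rel",
               "min_separation_um", "intensity_threshold", "elong_threshold"},
    "track": {"enabled", "gate_um", "max_gap", "arrest_threshold_min"},
}


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys anywhere in the config before any work starts."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _ALLOWED[""]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _ALLOWED.items():
        if not section or section not in cfg:
            continue
        block = cfg[section]
        if not isinstance(block, dict):
            raise ValueError(f"config section '{section}' must be a mapping")
        bad = set(block) - allowed
        if bad:
            raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")
    return cfg


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(cfg)


@dataclass
class StageRecord:
    stage: str
    params: dict
    wall_s: float
    outputs: list[str]


def _simulate(cfg: dict, seed: int, outdir: Path, frame_interval: float):
    block = cfg.get("simulate", {})
    scene_kwargs = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in block.items()
        if k in {"spheroid_radius_um", "n_nuclei", "volume_shape_vox",
                 "labeled_fraction", "mitotic_fraction", "rim_thickness_um"}
    }
    scene = _synthetic.SceneSpec(seed=seed, **scene_kwargs)
    optics = _synthetic.OpticsSpec(
        **{k: block[k] for k in ("attenuation_length_um",) if k in block}
    )
    stripes = _synthetic.StripeSpec(
        **{k: block[k] for k in ("noise_density", "noise_sd") if k in block}
    )
    events = tuple(tuple(e) for e in block.get("division_events", []))
    tl = _synthetic.TimelapseSpec(
        n_frames=int(block.get("n_frames", 1)),
        frame_interval_min=frame_interval,
        drift_per_frame_um=tuple(block.get("drift_per_frame_um", (0, 0, 0))),
        mitosis_duration_min=float(block.get("mitosis_duration_min", 45.0)),
        division_events=events,
        paclitaxel_mode=bool(block.get("paclitaxel_mode", False)),
        seed=seed,
    )
    vols, truth = _synthetic.render_timelapse(scene, optics, stripes, tl,
                                              keep_fields=False)
    outputs = []
    if block.get("save_stacks", False):
        for t, v in enumerate(vols):
            p = write_stack(v, outdir / f"simulated_t{t:03d}.tif")
            outputs.append(str(p))
    truth_json = outdir / "scene_truth.json"
    truth_json.write_text(json.dumps(_truth_to_json(truth), indent=2))
    outputs.append(str(truth_json))
    return vols, truth, outputs


def _truth_to_json(truth: _synthetic.SceneTruth) -> dict:
    return {
        "spheroid_center_um": truth.spheroid_center_um.tolist(),
        "spheroid_radius_um": truth.spheroid_radius_um,
        "nuclei": [
            {
                "id": n.id,
                "center_um": n.center_um.tolist(),
                "klass": n.klass,
                "labeled": n.labeled,
            }
            for n in truth.nuclei
        ],
        "daughters": {str(k): list(v) for k, v in truth.daughters.items()},
        "skipped_events": [list(e) for e in truth.skipped_events],
        "drift_um": [f.drift_um.tolist() for f in truth.frames],
    }


def detections_to_frame(dets: list[_detect.Detection], frame: int) -> pd.DataFrame:
    rows = []
    for d in dets:
        z, y, x = d.centroid_um
        rows.append({
            "frame": frame, "id": d.id, "x_um": x, "y_um": y, "z_um": z,
            "volume_um3": d.volume_um3, "mean_intensity": d.mean_intensity,
            "background_ratio": d.background_ratio, "elongation": d.elongation,
            "klass": d.klass, "depth_from_surface_um": d.depth_from_surface_um,
        })
    cols = ["frame", "id", "x_um", "y_um", "z_um", "volume_um3", "mean_intensity",
            "background_ratio", "elongation", "klass", "depth_from_surface_um"]
    return pd.DataFrame(rows, columns=cols)


def events_to_frame(events: list[_dynamics.MitoticEvent]) -> pd.DataFrame:
    rows = [{
        "track_id": e.track_id, "entry_frame": e.entry_frame,
        "exit_frame": e.exit_frame, "duration_min": e.duration_min,
        "outcome": e.outcome, "aligned": e.aligned,
        "parent_id": None,
    } for e in events]
    cols = ["track_id", "entry_frame", "exit_frame", "duration_min", "outcome",
            "aligned", "parent_id"]
    return pd.DataFrame(rows, columns=cols)


def events_from_frame(df: pd.DataFrame) -> list[_dynamics.MitoticEvent]:
    events = []
    for _, r in df.iterrows():
        aligned = r.get("aligned")
        if pd.isna(aligned):
            aligned = None
        else:
            aligned = bool(aligned)
        exit_frame = None if pd.isna(r.get("exit_frame")) else int(r["exit_frame"])
        events.append(_dynamics.MitoticEvent(
            track_id=int(r["track_id"]), entry_frame=int(r["entry_frame"]),
            exit_frame=exit_frame, duration_min=float(r["duration_min"]),
            outcome=str(r["outcome"]), aligned=aligned,
        ))
    return events


def process_volume(
    vol: ImageVolume, cfg: dict
) -> tuple[list[_detect.Detection], _detect.SpheroidFit | None]:
    """Detect, segment, classify and geolocate nuclei in one stack."""
    dblock = cfg.get("detect", {})
    params = _detect.DetectParams(
        min_radius_um=float(dblock.get("min_radius_um", 2.5)),
        max_radius_um=float(dblock.get("max_radius_um", 5.5)),
        threshold_rel=float(dblock.get("threshold_rel", 0.25)),
        min_separation_um=float(dblock.get("min_separation_um", 6.0)),
    )
    thr = _detect.ClassifyThresholds(
        intensity_threshold=float(dblock.get("intensity_threshold", 1.6)),
        elong_threshold=float(dblock.get("elong_threshold", 1.6)),
    )
    dets = _detect.detect_nuclei(vol, params)
    if not dets:
        return [], None
    dets, _ = _detect.segment_and_measure(vol, dets, params)
    dets = _detect.classify_mitotic(dets, thr)
    fit = None
    if len(dets) >= 10:
        try:
            fit = _detect.fit_spheroid(dets)
            dets = _detect.depth_from_surface(dets, fit)
        except ValueError:
            fit = None
    return dets, fit


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages in fixed order and write a manifest.

    Returns the artifact directory. Stage errors abort the run with the
    stage name attached.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else validate_config(dict(config))
    outdir = Path(output_dir or cfg.get("output_dir", "mitospim_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    frame_interval = float(cfg.get("frame_interval_min", 3.0))
    manifest: dict = {"config": cfg, "seed": seed, "stages": []}

    def record(stage: str, params: dict, t0: float, outputs: list[str]) -> None:
        manifest["stages"].append(asdict(StageRecord(
            stage=stage, params=params, wall_s=round(time.perf_counter() - t0, 3),
            outputs=outputs,
        )))

    try:
        # --- acquire ---
        truth = None
        if cfg.get("simulate", {}).get("enabled", False):
            t0 = time.perf_counter()
            frames, truth, outs = _simulate(cfg, seed, outdir, frame_interval)
            record("simulate", cfg.get("simulate", {}), t0, outs)
        elif cfg.get("inputs"):
            paths = cfg["inputs"]
            if isinstance(paths, str):
                paths = sorted(str(p) for p in Path().glob(paths))
            override = cfg.get("voxel_size_um")
            frames = [
                read_stack(p, tuple(override) if override else None) for p in paths
            ]
        else:
            raise ValueError("config enables no input: set simulate.enabled or inputs")

        # --- destripe ---
        dblock = cfg.get("destripe", {})
        if dblock.get("enabled", True):
            t0 = time.perf_counter()
            psi = _destripe.default_psi(
                float(dblock.get("sigma_along_um", 30.0)),
                float(dblock.get("sigma_across_um", 1.0)),
                frames[0].voxel_size_um,
            )
            model = _destripe.StripeModel(
                psi=psi,
                alpha=float(dblock.get("alpha", 0.2)),
                prior=str(dblock.get("prior", "l1")),
                max_iter=int(dblock.get("max_iter", 200)),
                tol=float(dblock.get("tol", 1e-4)),
            )
            frames = [_destripe.destripe_volume(f, model).clean for f in frames]
            record("destripe", {"alpha": model.alpha, "prior": model.prior}, t0, [])

        # --- fuse (two-view inputs only) ---
        fblock = cfg.get("fuse", {})
        if fblock.get("enabled", False):
            t0 = time.perf_counter()
            v180 = read_stack(fblock["view180"])
            transform = _register.register_opposing(frames[0], v180)
            fused = _register.fuse_views([frames[0], v180], [None, transform])
            frames = [fused] + frames[1:]
            p = write_stack(fused, outdir / "fused.tif")
            record("fuse", {"weights": fblock.get("weights", "ramp")}, t0, [str(p)])

        # --- drift correction ---
        drblock = cfg.get("driftcorrect", {})
        if drblock.get("enabled", len(frames) > 1) and len(frames) > 1:
            t0 = time.perf_counter()
            shifts_um, frames, scores = _register.correct_drift(
                frames, reference=str(drblock.get("reference", "first"))
            )
            df = pd.DataFrame({
                "frame": np.arange(len(frames)),
                "dx_um": shifts_um[:, 2], "dy_um": shifts_um[:, 1],
                "dz_um": shifts_um[:, 0], "score": scores,
            })
            p = outdir / "shifts.csv"
            df.to_csv(p, index=False)
            record("driftcorrect", {"reference": drblock.get("reference", "first")},
                   t0, [str(p)])

        # --- detect ---
        per_frame: list[list[_detect.Detection]] = []
        if cfg.get("detect", {}).get("enabled", True):
            t0 = time.perf_counter()
            tables = []
            for t, f in enumerate(frames):
                dets, _fit = process_volume(f, cfg)
                per_frame.append(dets)
                tables.append(detections_to_frame(dets, t))
            det_path = outdir / "detections.csv"
            pd.concat(tables, ignore_index=True).to_csv(det_path, index=False)
            record("detect", cfg.get("detect", {}), t0, [str(det_path)])

        # --- track ---
        if cfg.get("track", {}).get("enabled", len(frames) > 1) and per_frame and len(frames) > 1:
            t0 = time.perf_counter()
            tblock = cfg.get("track", {})
            tracks = _dynamics.link_tracks(
                per_frame,
                gate_um=float(tblock.get("gate_um", 10.0)),
                max_gap=int(tblock.get("max_gap", 1)),
            )
            events = _dynamics.extract_mitotic_events(
                tracks, frame_interval,
                arrest_threshold_min=float(tblock.get("arrest_threshold_min", 60.0)),
            )
            ev_path = outdir / "events.csv"
            events_to_frame(events).to_csv(ev_path, index=False)
            tr_path = outdir / "tracks.csv"
            pd.DataFrame([
                {"track_id": t.track_id, "frame": p.frame, "det_id": p.det_id,
                 "x_um": p.centroid_um[2], "y_um": p.centroid_um[1],
                 "z_um": p.centroid_um[0], "klass": p.klass,
                 "parent_id": t.parent_id}
                for t in tracks for p in t.points
            ]).to_csv(tr_path, index=False)
            record("track", tblock, t0, [str(ev_path), str(tr_path)])
    except Exception as e:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage '{stage}': {e}") from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def write_report(
    control_events_csv: str | Path,
    treated_events_csv: str | Path,
    out_path: str | Path,
) -> dict:
    """Compare two arms' event tables and write the machine-readable report."""
    ctrl = events_from_frame(pd.read_csv(control_events_csv))
    trt = events_from_frame(pd.read_csv(treated_events_csv))
    summary = _dynamics.compare_conditions(ctrl, trt)
    Path(out_path).write_text(json.dumps(summary, indent=2))
    return summary
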