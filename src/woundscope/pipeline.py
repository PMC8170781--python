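"""End-to-end pipeline: simulate/load -> segment -> track/density -> edge.

Driven by a YAML or JSON config file so a whole analysis is reproducible
from one artefact.  Config layout (all sections optional unless noted)::

    input: path/to/stack.tif        # or a directory of frames; omit when
    simulate:                       # simulating a scene instead
      n_frames: 6
      seed: 7                       # any SceneConfig field
    pixel_size_um: 1.4
    dt_min: 15
    method: adaptive                # adaptive | icd | idsd | canny
    weights: model.npz              # required for icd / idsd
    params: {sensitivity: 0.6}      # method-specific overrides
    tracking: {radius_px: 25}
    profiles: {n_columns: 50}
    edge: {dilation_radius_px: 15}
    output_dir: results             # required
    seed: 0

Every run writes masks (PNG), detections/tracks/profiles/edges (CSV), a
metrics report (JSON) and a log file echoing the config and seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as wio
from .cellscale import civ_field, civ_speed_profile, density_profile, track_sequence, velocity_profile
from .core import ImageSequence
from .popscale import GapClosedError, NoEdgeError, edge_from_canny, edge_from_cells, edge_from_idsd, edge_timeseries
from .segment_adaptive import AdaptiveSegmenter, mask_to_detections
from .synthgen import SceneConfig, simulate_scene
from .unet import UNetSegmenter, postprocess_icd

__all__ = ["run_pipeline", "load_config"]

_METHODS = ("adaptive", "icd", "idsd", "canny")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _get_sequence(cfg: dict) -> tuple[ImageSequence, object | None]:
    if "simulate" in cfg:
        scene = SceneConfig(**cfg["simulate"])
        seq, gt = simulate_scene(scene)
        return seq, gt
    if "input" not in cfg:
        raise ValueError("config needs either 'input' or 'simulate'")
    seq = wio.read_sequence(cfg["input"], cfg.get("pixel_size_um"), cfg.get("dt_min"))
    return seq, None


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured analysis; returns the report dictionary.

    The same config (and seed) always produces byte-identical CSV output.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    method = cfg.get("method", "adaptive")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    seq, gt = _get_sequence(cfg)
    params = dict(cfg.get("params", {}))
    report: dict = {"method": method, "n_frames": seq.n_frames, "seed": seed}

    # --- segmentation + detections -------------------------------------
    segmenter = None
    if method in ("icd", "idsd"):
        weights = cfg.get("weights")
        if not weights:
            raise ValueError(
                f"method {method!r} needs trained weights; pass 'weights: <model.npz>' "
                "(train one with `woundscope train`)"
            )
        segmenter = UNetSegmenter.load(weights)
    elif method == "adaptive":
        segmenter = AdaptiveSegmenter(**params).fit()

    dets_by_frame = []
    cell_masks = []
    contour_pairs = []
    for t in range(seq.n_frames):
        frame = seq[t]
        if method == "adaptive":
            mask = segmenter.predict(frame)
            dets = mask_to_detections(mask, t)
            cell_masks.append(mask)
        elif method == "icd":
            labels3 = segmenter.predict(frame)
            dets, mask = postprocess_icd(labels3, frame_idx=t, **cfg.get("postprocess", {}))
            cell_masks.append(mask)
        elif method == "idsd":
            mask = segmenter.predict(frame) == 1
            dets = []
            cell_masks.append(mask)
        else:  # canny: population scale only
            dets = []
            cell_masks.append(None)
        dets_by_frame.append(dets)

    # --- edges ----------------------------------------------------------
    edge_cfg = dict(cfg.get("edge", {}))
    for t in range(seq.n_frames):
        try:
            if method == "canny":
                left, right, _ = edge_from_canny(
                    seq[t], pixel_size_um=seq.pixel_size_um, frame=t, **edge_cfg
                )
            elif method == "idsd":
                left, right, _ = edge_from_idsd(cell_masks[t], seq.pixel_size_um, frame=t)
            else:
                left, right, _ = edge_from_cells(
                    cell_masks[t], pixel_size_um=seq.pixel_size_um, frame=t, **edge_cfg
                )
            contour_pairs.append((left, right))
        except (GapClosedError, NoEdgeError):
            contour_pairs.append(None)
    series = edge_timeseries(contour_pairs, seq.dt_min)
    report["closure_time_min"] = series.closure_time_min
    report["gap_width_mm"] = [round(g, 6) for g in series.gap_width_mm.tolist()]

    # --- cell-scale metrics ---------------------------------------------
    h, w = seq.frame_shape
    prof_cfg = dict(cfg.get("profiles", {}))
    n_columns = int(prof_cfg.get("n_columns", 50))
    if any(dets_by_frame):
        density = density_profile(dets_by_frame[0], w, h, seq.pixel_size_um, n_columns)
        wio.profile_to_csv(density, out_dir / "density.csv")
        radius = float(cfg.get("tracking", {}).get("radius_px", 25.0))
        tracks = track_sequence(dets_by_frame, radius, seq.pixel_size_um, seq.dt_min)
        wio.tracks_to_csv(tracks, out_dir / "tracks.csv")
        speeds = [s for tr in tracks for s in tr.speeds_mm_h]
        report["n_tracks"] = len(tracks)
        report["mean_speed_mm_h"] = float(np.mean(speeds)) if speeds else None
        velocity = velocity_profile(tracks, w, seq.pixel_size_um, n_columns)
        wio.profile_to_csv(velocity, out_dir / "velocity.csv")
        report["mean_cell_count"] = float(np.mean([len(d) for d in dets_by_frame]))
    if cfg.get("civ") and seq.n_frames >= 2:
        res = civ_field(seq[0], seq[1], pixel_size_um=seq.pixel_size_um, dt_min=seq.dt_min)
        wio.profile_to_csv(civ_speed_profile(res, w, seq.pixel_size_um, n_columns), out_dir / "civ.csv")
        report["civ_mean_speed_mm_h"] = float(res.speed_mm_h[res.valid].mean()) if res.valid.any() else None

    # --- outputs ---------------------------------------------------------
    wio.detections_to_csv(dets_by_frame, out_dir / "detections.csv")
    wio.edges_to_csv(series, out_dir / "edges.csv")
    for t, mask in enumerate(cell_masks):
        if mask is not None:
            wio.write_mask_png(np.asarray(mask).astype(np.uint8) * 255, out_dir / f"mask_{t:04d}.png", scale=False)
    if gt is not None:
        wio.write_ground_truth(gt, out_dir)
        wio.write_sequence(seq, out_dir / "frames.tif")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    log = {"config": {k: v for k, v in cfg.items() if k != "output_dir"}, "seed": seed}
    if gt is not None:
        log["scene_config"] = asdict(gt.config)
    (out_dir / "run.log").write_text(json.dumps(log, indent=2, default=str))
    return report
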