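"""Reading and writing the standard formats used by the pipeline.

Image sequences come in as multi-page TIFF stacks or directories of
numbered PNG/TIFF frames (natural sort order, so ``frame10`` follows
``frame2``); integer inputs are scaled to [0, 1] by their dtype maximum.
Outputs are plain formats: float TIFF stacks, 8-bit PNG masks, CSV tables
and JSON sidecars.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cellscale import CellDetection, Profile, Track
from .core import ImageSequence

__all__ = [
    "read_sequence",
    "write_sequence",
    "write_mask_png",
    "detections_to_csv",
    "detections_from_csv",
    "tracks_to_csv",
    "profile_to_csv",
    "edges_to_csv",
    "write_ground_truth",
]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _to_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return (arr / np.iinfo(arr.dtype).max).astype(np.float32)
    return arr.astype(np.float32)


def read_sequence(
    path: str | Path | list,
    pixel_size_um: float | None = None,
    dt_min: float | None = None,
) -> ImageSequence:
    """Load an image sequence from a TIFF stack, a directory of numbered
    frames, or an explicit file list.

    A JSON sidecar named ``<stem>.json`` (or ``sequence.json`` in a frame
    directory) may provide ``pixel_size_um`` and ``dt_min``; explicit
    arguments win.
    """
    meta: dict = {}
    if isinstance(path, (list, tuple)):
        files = [Path(p) for p in path]
        frames = [_read_one(p) for p in files]
    else:
        path = Path(path)
        if path.is_dir():
            files = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
                key=lambda p: _natural_key(p.name),
            )
            if not files:
                raise FileNotFoundError(f"no image frames found in {path}")
            frames = [_read_one(p) for p in files]
            sidecar = path / "sequence.json"
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
        elif path.suffix.lower() == ".png":
            frames = [_read_one(path)]
        else:
            if not path.exists():
                raise FileNotFoundError(f"unreadable file: {path}")
            stack = tifffile.imread(path)
            frames = [_to_float(f) for f in (stack if stack.ndim == 3 else stack[None])]
            sidecar = path.with_suffix(".json")
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame shapes: {sorted(shapes)}")
    return ImageSequence(
        np.stack(frames),
        pixel_size_um=pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 1.4),
        dt_min=dt_min if dt_min is not None else meta.get("dt_min", 15.0),
        metadata=meta,
    )


def _read_one(p: Path) -> np.ndarray:
    if not p.exists():
        raise FileNotFoundError(f"unreadable file: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        return _to_float(tifffile.imread(p))
    return _to_float(iio.imread(p))


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write frames as a float32 TIFF stack plus a JSON sidecar with the
    calibration, so a read round-trips bit-exactly."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32), photometric='minisblack')
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"pixel_size_um": seq.pixel_size_um, "dt_min": seq.dt_min, **seq.metadata}, default=str)
    )


def write_mask_png(mask: np.ndarray, path: str | Path, scale: bool = True) -> None:
    """8-bit PNG label/binary mask; ``scale`` stretches labels for viewing."""
    mask = np.asarray(mask)
    if scale and mask.max() > 0:
        out = (mask.astype(float) / mask.max() * 255).astype(np.uint8)
    else:
        out = mask.astype(np.uint8)
    iio.imwrite(Path(path), out)


_DET_HEADER = "# 0-based pixel coordinates: x = column, y = row\n"


def detections_to_csv(dets_by_frame: list[list[CellDetection]], path: str | Path) -> None:
    rows = [
        (d.frame, d.id, d.centroid_x_px, d.centroid_y_px, d.area_px2)
        for dets in dets_by_frame
        for d in dets
    ]
    df = pd.DataFrame(rows, columns=["frame", "id", "x_px", "y_px", "area_px2"])
    with open(path, "w") as fh:
        fh.write(_DET_HEADER)
        df.to_csv(fh, index=False)


def detections_from_csv(path: str | Path) -> list[list[CellDetection]]:
    df = pd.read_csv(path, comment="#")
    out: list[list[CellDetection]] = []
    for frame, grp in df.groupby("frame", sort=True):
        while len(out) < int(frame):
            out.append([])
        out.append(
            [
                CellDetection(int(r.frame), int(r.id), float(r.x_px), float(r.y_px), float(r.area_px2))
                for r in grp.itertuples()
            ]
        )
    return out


def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for k, d in enumerate(tr.detections):
            speed = tr.speeds_mm_h[k] if k < len(tr.speeds_mm_h) else np.nan
            rows.append((tr.track_id, d.frame, d.centroid_x_px, d.centroid_y_px, speed))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "speed_mm_h"])
    with open(path, "w") as fh:
        fh.write(_DET_HEADER)
        df.to_csv(fh, index=False)


def profile_to_csv(profile: Profile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "column_index": np.arange(profile.n_columns),
            "x_left_px": profile.edges_px[:-1],
            "x_center_mm": profile.centers_mm,
            "value": profile.values,
            "count": profile.counts,
            "defined": profile.defined.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# value units: {profile.units}\n")
        df.to_csv(fh, index=False)


def edges_to_csv(series, path: str | Path) -> None:
    """Edge time series as (frame, side, length_mm, mean_x_mm)."""
    rows = []
    for side in ("left", "right"):
        for t in range(series.n_frames):
            rows.append((t, side, series.length_mm[side][t], series.mean_x_mm[side][t]))
    pd.DataFrame(rows, columns=["frame", "side", "length_mm", "mean_x_mm"]).to_csv(path, index=False)


def write_ground_truth(gt, out_dir: str | Path) -> None:
    """Ground-truth CSV (frame, cell_id, x_px, y_px, area_px2, vx, vy)
    plus the scene config as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt.cells.to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "scene_config.json").write_text(gt.config.to_json())
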