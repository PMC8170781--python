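"""Cell-scale analytics: detections, tracking, column profiles, velocimetry.

Tracking links detections of consecutive frames by a globally greedy
nearest-neighbor rule bounded by a maximum motion radius R: all candidate
pairs within R are sorted by distance and accepted only if both endpoints
are still unmatched.  This prevents two cells from claiming the same
successor.  A track ends at its first missed link (no gap closing).

Column profiles follow the convention of dividing the image into 50
columns perpendicular to the gap: densities are counts per column area
(cells/mm^2, with counts/mm width-normalisation available as an option),
speeds are column means of the per-step velocity magnitude.

Cell image velocimetry (CIV) is a basic two-pass normalized
cross-correlation PIV: a coarse pass at the largest interrogation-area (IA)
size predicts the shift for the final pass at the smallest IA size, on a
50%-overlap grid, with three-point Gaussian sub-pixel peak interpolation
and a peak-ratio validity test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .core import px_per_frame_to_mm_per_h

__all__ = [
    "CellDetection",
    "Track",
    "Profile",
    "CIVConfig",
    "CIVResult",
    "density_profile",
    "profile_from_samples",
    "link_frames",
    "track_sequence",
    "velocity_profile",
    "civ_field",
    "civ_speed_profile",
]


@dataclass
class CellDetection:
    """One labelled cell on one frame: centroid of the cell area + unique id."""

    frame: int
    id: int
    centroid_x_px: float
    centroid_y_px: float
    area_px2: float


@dataclass
class Track:
    """A cross-frame linkage of one cell.

    ``speeds_mm_h[i]`` is the speed of the step from ``detections[i]`` to
    ``detections[i+1]``.
    """

    track_id: int
    detections: list[CellDetection] = field(default_factory=list)
    step_px: list[float] = field(default_factory=list)
    speeds_mm_h: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class Profile:
    """A column-binned scalar vs x: density (cells/mm^2) or speed (mm/h).

    Columns partition [0, width_px) into ``n_columns`` equal half-open bins
    (the last bin is closed).  ``defined`` flags columns with at least one
    contributing sample.
    """

    values: np.ndarray
    counts: np.ndarray
    edges_px: np.ndarray
    pixel_size_um: float
    units: str
    defined: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.values)

    @property
    def edges_mm(self) -> np.ndarray:
        return self.edges_px * self.pixel_size_um / 1000.0

    @property
    def centers_mm(self) -> np.ndarray:
        return 0.5 * (self.edges_mm[:-1] + self.edges_mm[1:])


def _column_index(x: np.ndarray, width_px: float, n_columns: int) -> np.ndarray:
    idx = np.floor(np.asarray(x, dtype=float) * n_columns / width_px).astype(int)
    return np.clip(idx, 0, n_columns - 1)


def density_profile(
    detections: list[CellDetection],
    width_px: int,
    height_px: int,
    pixel_size_um: float,
    n_columns: int = 50,
    normalisation: str = "area",
) -> Profile:
    """Column-wise cell density from one frame's detections.

    Each cell is assigned to the column containing its centroid x; the
    count is divided by the column area in mm^2 (``normalisation="area"``)
    or by the column width in mm (``normalisation="width"``).
    """
    if n_columns > width_px:
        raise ValueError("more columns than pixels")
    if normalisation not in ("area", "width"):
        raise ValueError("normalisation must be 'area' or 'width'")
    counts = np.zeros(n_columns, dtype=int)
    if detections:
        xs = np.array([d.centroid_x_px for d in detections])
        if (xs < 0).any() or (xs >= width_px).any():
            raise ValueError("centroid outside image bounds")
        np.add.at(counts, _column_index(xs, width_px, n_columns), 1)
    col_w_mm = (width_px / n_columns) * pixel_size_um / 1000.0
    if normalisation == "area":
        denom = col_w_mm * height_px * pixel_size_um / 1000.0
        units = "cells/mm^2"
    else:
        denom = col_w_mm
        units = "cells/mm"
    edges = np.linspace(0, width_px, n_columns + 1)
    return Profile(
        values=counts / denom,
        counts=counts,
        edges_px=edges,
        pixel_size_um=pixel_size_um,
        units=units,
        defined=np.ones(n_columns, dtype=bool),
    )


def profile_from_samples(
    x_px: np.ndarray,
    values: np.ndarray,
    width_px: int,
    pixel_size_um: float,
    n_columns: int = 50,
    units: str = "mm/h",
) -> Profile:
    """Column-wise mean of scalar samples located at x positions."""
    x_px = np.asarray(x_px, dtype=float)
    values = np.asarray(values, dtype=float)
    sums = np.zeros(n_columns)
    counts = np.zeros(n_columns, dtype=int)
    if x_px.size:
        idx = _column_index(x_px, width_px, n_columns)
        np.add.at(sums, idx, values)
        np.add.at(counts, idx, 1)
    defined = counts > 0
    out = np.full(n_columns, np.nan)
    out[defined] = sums[defined] / counts[defined]
    return Profile(
        values=out,
        counts=counts,
        edges_px=np.linspace(0, width_px, n_columns + 1),
        pixel_size_um=pixel_size_um,
        units=units,
        defined=defined,
    )


@dataclass
class LinkResult:
    matches: list[tuple[int, int]]
    unmatched_t: list[int]
    unmatched_t1: list[int]


def link_frames(dets_t: list[CellDetection], dets_t1: list[CellDetection], R_px: float) -> LinkResult:
    """Greedy global nearest-neighbor matching between two frames.

    Candidate pairs with Euclidean centroid distance <= R are sorted by
    (distance, id_t, id_t1) and accepted when both endpoints are free.
    Returns index pairs into the input lists plus the unmatched indices
    (unmatched previous-frame detections terminate their tracks, unmatched
    next-frame detections start new ones).
    """
    if R_px <= 0:
        raise ValueError("R_px must be positive")
    cands = []
    for i, a in enumerate(dets_t):
        for j, b in enumerate(dets_t1):
            d = float(np.hypot(a.centroid_x_px - b.centroid_x_px, a.centroid_y_px - b.centroid_y_px))
            if d <= R_px:
                cands.append((d, a.id, b.id, i, j))
    cands.sort()
    used_t: set[int] = set()
    used_t1: set[int] = set()
    matches = []
    for _, _, _, i, j in cands:
        if i in used_t or j in used_t1:
            continue
        used_t.add(i)
        used_t1.add(j)
        matches.append((i, j))
    unmatched_t = [i for i in range(len(dets_t)) if i not in used_t]
    unmatched_t1 = [j for j in range(len(dets_t1)) if j not in used_t1]
    return LinkResult(matches, unmatched_t, unmatched_t1)


def track_sequence(
    dets_by_frame: list[list[CellDetection]],
    R_px: float,
    pixel_size_um: float,
    dt_min: float,
) -> list[Track]:
    """Chain :func:`link_frames` over consecutive frames into tracks.

    Per-step speed is distance * pixel size / frame interval, in mm/h.
    """
    tracks: list[Track] = []
    open_by_det: dict[int, Track] = {}  # index in current frame -> track
    next_id = 0
    for t, dets in enumerate(dets_by_frame):
        if t == 0:
            for i, d in enumerate(dets):
                tr = Track(next_id, [d])
                next_id += 1
                tracks.append(tr)
                open_by_det[i] = tr
            continue
        res = link_frames(dets_by_frame[t - 1], dets, R_px)
        new_open: dict[int, Track] = {}
        for i, j in res.matches:
            tr = open_by_det[i]
            prev = tr.detections[-1]
            d = dets[j]
            dist = float(np.hypot(d.centroid_x_px - prev.centroid_x_px, d.centroid_y_px - prev.centroid_y_px))
            tr.detections.append(d)
            tr.step_px.append(dist)
            tr.speeds_mm_h.append(px_per_frame_to_mm_per_h(dist, pixel_size_um, dt_min))
            new_open[j] = tr
        for j in res.unmatched_t1:
            tr = Track(next_id, [dets[j]])
            next_id += 1
            tracks.append(tr)
            new_open[j] = tr
        open_by_det = new_open  # unmatched old tracks terminate here
    return tracks


def velocity_profile(
    tracks: list[Track],
    width_px: int,
    pixel_size_um: float,
    n_columns: int = 50,
) -> Profile:
    """Column-averaged speed: each step's magnitude is assigned to the
    column of its start centroid; columns without steps are undefined."""
    xs = []
    vs = []
    for tr in tracks:
        for k, v in enumerate(tr.speeds_mm_h):
            xs.append(tr.detections[k].centroid_x_px)
            vs.append(v)
    return profile_from_samples(np.array(xs), np.array(vs), width_px, pixel_size_um, n_columns)


# ---------------------------------------------------------------------------
# Cell image velocimetry
# ---------------------------------------------------------------------------


@dataclass
class CIVConfig:
    """Two-pass cross-correlation settings.

    ``ia_min_px``/``ia_max_px`` are the final and coarse interrogation-area
    sizes (powers of two); ``overlap`` the fractional IA overlap of the
    sampling grid; vectors whose correlation peak ratio (highest over
    second-highest peak) falls below ``snr_min`` are flagged invalid.
    """

    ia_min_px: int = 32
    ia_max_px: int = 64
    overlap: float = 0.5
    snr_min: float = 1.5
    subpixel: str = "gauss3pt"

    def validate(self) -> None:
        for s in (self.ia_min_px, self.ia_max_px):
            if s < 4 or (s & (s - 1)) != 0:
                raise ValueError("IA sizes must be powers of two >= 4")
        if self.ia_min_px > self.ia_max_px:
            raise ValueError("ia_min_px must not exceed ia_max_px")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if self.subpixel != "gauss3pt":
            raise ValueError("unknown subpixel estimator")


@dataclass
class CIVResult:
    """Vector field on the IA grid: positions (px), shifts (px/frame),
    validity flags and speeds (mm/h)."""

    x_px: np.ndarray
    y_px: np.ndarray
    u_px: np.ndarray
    v_px: np.ndarray
    valid: np.ndarray
    speed_mm_h: np.ndarray


def _correlate_window(template: np.ndarray, search: np.ndarray):
    """NCC of a template against every aligned window of a larger search
    region (top-left convention, no padding).

    Returns (peak_y, peak_x, peak ratio): ``corr[k, l]`` correlates the
    template with ``search[k:k+ia, l:l+ia]``, with a 3-point Gaussian
    sub-pixel fit applied to the peak coordinates.
    """
    if template.std() < 1e-9 or search.std() < 1e-9:
        return None
    corr = match_template(search, template, pad_input=False)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    p1 = corr[peak]
    # second peak outside an exclusion zone scaled to the IA (cell textures
    # are smooth, so the main correlation peak is several pixels wide)
    excl = max(2, template.shape[0] // 8)
    masked = corr.copy()
    y0, x0 = peak
    masked[max(y0 - excl, 0) : y0 + excl + 1, max(x0 - excl, 0) : x0 + excl + 1] = -np.inf
    p2 = masked.max()
    ratio = np.inf if p2 <= 1e-12 else float(p1 / p2)
    # 3-point Gaussian sub-pixel fit per axis
    dy = dx = 0.0
    if 0 < y0 < corr.shape[0] - 1:
        cm, c0, cp = corr[y0 - 1, x0], p1, corr[y0 + 1, x0]
        if cm > 0 and c0 > 0 and cp > 0:
            denom = np.log(cm) - 2 * np.log(c0) + np.log(cp)
            if denom < -1e-12:
                dy = float(np.clip(0.5 * (np.log(cm) - np.log(cp)) / denom, -1, 1))
    if 0 < x0 < corr.shape[1] - 1:
        cm, c0, cp = corr[y0, x0 - 1], p1, corr[y0, x0 + 1]
        if cm > 0 and c0 > 0 and cp > 0:
            denom = np.log(cm) - 2 * np.log(c0) + np.log(cp)
            if denom < -1e-12:
                dx = float(np.clip(0.5 * (np.log(cm) - np.log(cp)) / denom, -1, 1))
    return y0 + dy, x0 + dx, ratio


def _median_validate(rows: np.ndarray, valid: np.ndarray, eps: float = 0.1, thresh: float = 2.0) -> np.ndarray:
    """Normalized median test (universal outlier detection).

    Each vector is compared with the median of its up-to-8 nearest grid
    neighbours; vectors whose normalized residual exceeds ``thresh`` are
    flagged invalid.  This catches plausible-looking false peaks, e.g. at
    image borders where the displaced content has left the frame.
    """
    ys = np.unique(rows[:, 0])
    xs = np.unique(rows[:, 1])
    ny, nx = len(ys), len(xs)
    if ny * nx != len(rows):
        return valid  # irregular grid: skip the test
    yi = np.searchsorted(ys, rows[:, 0]).reshape(ny * nx)
    xi = np.searchsorted(xs, rows[:, 1])
    gu = np.full((ny, nx), np.nan)
    gv = np.full((ny, nx), np.nan)
    gu[yi, xi] = np.where(valid, rows[:, 3], np.nan)
    gv[yi, xi] = np.where(valid, rows[:, 2], np.nan)
    out = valid.copy()
    for k in range(len(rows)):
        if not valid[k]:
            continue
        i, j = yi[k], xi[k]
        nb_u, nb_v = [], []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0 or not (0 <= i + di < ny and 0 <= j + dj < nx):
                    continue
                if np.isfinite(gu[i + di, j + dj]):
                    nb_u.append(gu[i + di, j + dj])
                    nb_v.append(gv[i + di, j + dj])
        if len(nb_u) < 3:
            continue
        for comp, g in ((nb_u, gu[i, j]), (nb_v, gv[i, j])):
            med = np.median(comp)
            rm = np.median(np.abs(np.asarray(comp) - med))
            if np.abs(g - med) / (rm + eps) > thresh:
                out[k] = False
                break
    return out


def _pass_grid(shape, ia, overlap):
    step = max(1, int(round(ia * (1.0 - overlap))))
    ys = np.arange(0, shape[0] - ia + 1, step)
    xs = np.arange(0, shape[1] - ia + 1, step)
    return ys, xs


def _single_pass(frame_t, frame_t1, ia, overlap, pred=None, pred_pos=None):
    h, w = frame_t.shape
    ys, xs = _pass_grid(frame_t.shape, ia, overlap)
    margin = ia // 2
    out = []
    for y0 in ys:
        for x0 in xs:
            template = frame_t[y0 : y0 + ia, x0 : x0 + ia]
            cy, cx = y0 + ia / 2.0, x0 + ia / 2.0
            py = px = 0
            if pred is not None:
                k = np.argmin((pred_pos[:, 0] - cy) ** 2 + (pred_pos[:, 1] - cx) ** 2)
                py, px = int(round(pred[k][0])), int(round(pred[k][1]))
            sy0 = y0 + py - margin
            sx0 = x0 + px - margin
            sy0 = int(np.clip(sy0, 0, h - ia - 2 * margin)) if h >= ia + 2 * margin else 0
            sx0 = int(np.clip(sx0, 0, w - ia - 2 * margin)) if w >= ia + 2 * margin else 0
            search = frame_t1[sy0 : sy0 + ia + 2 * margin, sx0 : sx0 + ia + 2 * margin]
            res = _correlate_window(template, search)
            if res is None:
                out.append((cy, cx, 0.0, 0.0, 0.0))
                continue
            ky, kx, ratio = res
            # matched window top-left in frame_t1 is (sy0 + ky, sx0 + kx);
            # displacement is relative to the template top-left (y0, x0)
            out.append((cy, cx, sy0 + ky - y0, sx0 + kx - x0, ratio))
    return np.array(out)


def civ_field(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    cfg: CIVConfig | None = None,
    pixel_size_um: float = 1.4,
    dt_min: float = 15.0,
) -> CIVResult:
    """Two-pass NCC velocimetry between two consecutive frames."""
    cfg = cfg or CIVConfig()
    cfg.validate()
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must have the same shape")
    if min(frame_t.shape) < cfg.ia_max_px:
        raise ValueError("frames smaller than the largest interrogation area")

    coarse = _single_pass(frame_t, frame_t1, cfg.ia_max_px, cfg.overlap)
    ok = _median_validate(coarse, coarse[:, 4] >= cfg.snr_min)
    pred = coarse[ok][:, 2:4] if ok.any() else np.zeros((1, 2))
    pred_pos = coarse[ok][:, 0:2] if ok.any() else np.array([[frame_t.shape[0] / 2, frame_t.shape[1] / 2]])

    fine = _single_pass(frame_t, frame_t1, cfg.ia_min_px, cfg.overlap, pred=pred, pred_pos=pred_pos)
    v_px = np.hypot(fine[:, 2], fine[:, 3])
    valid = _median_validate(fine, fine[:, 4] >= cfg.snr_min)
    speed = px_per_frame_to_mm_per_h(v_px, pixel_size_um, dt_min)
    return CIVResult(
        x_px=fine[:, 1],
        y_px=fine[:, 0],
        u_px=fine[:, 3],
        v_px=fine[:, 2],
        valid=valid,
        speed_mm_h=speed,
    )


def civ_speed_profile(
    result: CIVResult,
    width_px: int,
    pixel_size_um: float,
    n_columns: int = 50,
) -> Profile:
    """Column-averaged CIV speed over the valid vectors."""
    return profile_from_samples(
        result.x_px[result.valid],
        result.speed_mm_h[result.valid],
        width_px,
        pixel_size_um,
        n_columns,
    )
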