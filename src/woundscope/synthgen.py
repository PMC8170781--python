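"""Synthetic wound-healing scenes with complete ground truth.

Emulates a scratch/migration assay: two confluent cell monolayers separated
by a vertical cell-free gap (about 500 um wide by default), imaged every
15 min.  Cells are rendered as textured ellipses on a darker background with
an optional linear illumination gradient.  Cells near the gap-facing front
("border" cells) migrate toward the gap centre at a directed speed; interior
cells perform an isotropic random walk.  Every frame carries full ground
truth: per-cell records (id, centroid, area, velocity), a per-pixel cell-id
label map, a monolayer/gap mask, and the true leading-edge position per row.

The generator is fully deterministic for a fixed config (including its
seed): identical configs produce bit-identical sequences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .core import ImageSequence, mm_per_h_to_px_per_frame, px_per_frame_to_mm_per_h

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "simulate_scene",
    "add_gaussian_noise",
    "render_labels",
]


@dataclass
class SceneConfig:
    """Parameters of one synthetic wound-healing scene.

    Speeds are physical (mm/h); the renderer converts them to pixels per
    frame from ``pixel_size_um`` and ``dt_min``.  ``asymmetry`` in [-1, 1]
    biases the directed edge speed: the left (upstream) front advances at
    ``v_edge_mm_h * (1 + asymmetry)`` and the right (downstream) front at
    ``v_edge_mm_h * (1 - asymmetry)``, emulating the faster upstream edge
    observed under flow.  ``deformation`` adds per-frame fractional jitter
    to the ellipse axes (shape change without net motion).
    """

    width_px: int = 1024
    height_px: int = 384
    pixel_size_um: float = 1.4
    dt_min: float = 15.0
    n_frames: int = 10
    gap_width_um: float = 500.0
    cell_density_per_mm2: float = 600.0
    cell_radius_um_mean: float = 18.0
    cell_radius_um_sd: float = 3.0
    v_edge_mm_h: float = 0.03
    v_inner_mm_h: float = 0.02
    asymmetry: float = 0.0
    division_rate_per_h: float = 0.0
    deformation: float = 0.0
    illumination_gradient: float = 0.0
    texture_contrast: float = 0.3
    background_level: float = 0.1
    substrate_texture: float = 0.02
    cell_peak_intensity: float = 0.75
    border_band_factor: float = 2.2
    seed: int = 0

    def validate(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0 or self.dt_min <= 0:
            raise ValueError("pixel_size_um and dt_min must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.gap_width_um <= 0:
            raise ValueError("gap_width_um must be positive")
        if self.gap_width_um >= self.width_px * self.pixel_size_um:
            raise ValueError("gap is wider than the image")
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [-1, 1]")
        if self.cell_radius_um_mean <= 0 or self.cell_density_per_mm2 <= 0:
            raise ValueError("cell size and density must be positive")
        for name in ("v_edge_mm_h", "v_inner_mm_h", "division_rate_per_h", "deformation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        return cls(**json.loads(text))


@dataclass
class GroundTruth:
    """Per-frame ground truth of a simulated scene.

    ``cells`` is a table with one row per rendered cell per frame:
    (frame, cell_id, x_px, y_px, area_px2, vx_mm_h, vy_mm_h).  The velocity
    at frame t is the forward difference (position at t+1 minus t) over the
    frame interval; the last frame repeats the previous step.  ``label_maps``
    holds per-pixel cell ids (0 = background); ``monolayer_masks`` the
    2-class monolayer(1)/gap(0) view; ``edges`` the true leading-edge x
    position per row, shape (T, 2, H) with index 0 = left, 1 = right.
    """

    cells: pd.DataFrame
    label_maps: np.ndarray
    monolayer_masks: np.ndarray
    edges: np.ndarray
    config: SceneConfig
    _class_masks: dict = field(default_factory=dict, repr=False)

    def frame_cells(self, t: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == t]

    def n_cells(self, t: int) -> int:
        return int((self.cells["frame"] == t).sum())

    def class_masks(self, border_width_px: int = 2) -> np.ndarray:
        """3-class masks (background=0, cell=1, border=2), cached per width."""
        if border_width_px not in self._class_masks:
            self._class_masks[border_width_px] = render_labels(self, border_width_px)
        return self._class_masks[border_width_px]

    def gap_mask(self, t: int) -> np.ndarray:
        """Boolean mask of the true cell-free gap at frame t."""
        return self.monolayer_masks[t] == 0


class _Cell:
    __slots__ = ("cid", "x", "y", "a", "b", "theta", "side", "border", "drift", "tex")

    def __init__(self, cid, x, y, a, b, theta, side, border, drift, tex):
        self.cid = cid
        self.x = x
        self.y = y
        self.a = a  # semi-axis along theta, px
        self.b = b
        self.theta = theta
        self.side = side  # 0 = left monolayer, 1 = right
        self.border = border  # full directed migration toward the gap centre
        self.drift = drift  # directed-speed factor in [0, 1], decays with depth
        self.tex = tex  # (ntex, ntex) value-noise grid in cell-local coords


_NTEX = 17


def _place_monolayer(rng, cfg: SceneConfig, x_lo, x_hi, side, r_mean_px, next_id):
    """Dart-throw cell centres with a minimum-separation constraint."""
    area_mm2 = (x_hi - x_lo) * cfg.height_px * (cfg.pixel_size_um / 1000.0) ** 2
    n_target = max(1, int(round(cfg.cell_density_per_mm2 * area_mm2)))
    d_min = 1.9 * r_mean_px
    # keep whole ellipses inside the image so ground-truth centroids match
    # the rendered regions; the gap-facing side is not clamped
    m = 1.6 * r_mean_px
    if side == 0:
        lo, hi = m, x_hi  # front cells may protrude into the gap
    else:
        lo, hi = x_lo, cfg.width_px - m
    pts = []
    attempts = 0
    while len(pts) < n_target and attempts < 60 * n_target:
        attempts += 1
        x = rng.uniform(lo, hi)
        y = rng.uniform(m, cfg.height_px - m)
        if all((x - p[0]) ** 2 + (y - p[1]) ** 2 >= d_min**2 for p in pts):
            pts.append((x, y))
    cells = []
    sd_px = cfg.cell_radius_um_sd / cfg.pixel_size_um
    band = cfg.border_band_factor * r_mean_px
    front = x_hi if side == 0 else x_lo
    lam = 4.0 * r_mean_px  # depth scale of the follower drift behind the front
    for x, y in pts:
        r = float(np.clip(rng.normal(r_mean_px, sd_px), 2.0, 1.35 * r_mean_px))
        ecc = rng.uniform(0.75, 1.0)
        theta = rng.uniform(0, np.pi)
        tex = rng.random((_NTEX, _NTEX))
        depth = abs(x - front)
        border = depth <= band
        drift = 1.0 if border else float(np.exp(-(depth - band) / lam))
        cells.append(_Cell(next_id, x, y, r / np.sqrt(ecc), r * np.sqrt(ecc), theta, side, border, drift, tex))
        next_id += 1
    return cells, next_id


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    if hi <= lo:
        return float(np.clip(v, lo, hi))
    span = hi - lo
    v = (v - lo) % (2.0 * span)
    return float(lo + (2.0 * span - v if v > span else v))


def _bilinear(grid: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sample a small grid at fractional coordinates in [-1.2, 1.2]^2."""
    n = grid.shape[0]
    gu = np.clip((u + 1.2) / 2.4 * (n - 1), 0, n - 1.001)
    gv = np.clip((v + 1.2) / 2.4 * (n - 1), 0, n - 1.001)
    i0 = gu.astype(int)
    j0 = gv.astype(int)
    fu = gu - i0
    fv = gv - j0
    return (
        grid[i0, j0] * (1 - fu) * (1 - fv)
        + grid[i0 + 1, j0] * fu * (1 - fv)
        + grid[i0, j0 + 1] * (1 - fu) * fv
        + grid[i0 + 1, j0 + 1] * fu * fv
    )


def _render_frame(cells, cfg: SceneConfig, substrate: np.ndarray | None = None):
    """Render one frame and its cell-id label map.

    ``substrate`` is a static per-scene intensity field (visible wherever
    no cell outshines it); because it does not move between frames it
    anchors image correlations the way the real culture substrate does.
    """
    h, w = cfg.height_px, cfg.width_px
    xs = np.arange(w)
    bg = cfg.background_level + cfg.illumination_gradient * (xs / max(w - 1, 1) - 0.5)
    frame = np.tile(np.clip(bg, 0.0, 1.0), (h, 1)).astype(np.float64)
    if substrate is not None:
        frame = np.clip(frame + substrate, 0.0, 1.0)
    labels = np.zeros((h, w), dtype=np.int32)
    best_rho2 = np.full((h, w), np.inf)
    areas = {}
    for c in cells:
        rmax = max(c.a, c.b) + 1.0
        x0 = max(int(np.floor(c.x - rmax)), 0)
        x1 = min(int(np.ceil(c.x + rmax)) + 1, w)
        y0 = max(int(np.floor(c.y - rmax)), 0)
        y1 = min(int(np.ceil(c.y + rmax)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            areas[c.cid] = 0
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = xx - c.x
        dy = yy - c.y
        ct, st = np.cos(c.theta), np.sin(c.theta)
        u = (dx * ct + dy * st) / c.a
        v = (-dx * st + dy * ct) / c.b
        rho2 = u * u + v * v
        inside = rho2 <= 1.0
        if not inside.any():
            areas[c.cid] = 0
            continue
        tex = 1.0 + cfg.texture_contrast * (2.0 * _bilinear(c.tex, u, v) - 1.0)
        # steep radial falloff: bright cell bodies with dim rims, so
        # neighbouring cells stay visually separated as in phase imaging
        intensity = cfg.cell_peak_intensity * np.exp(-2.2 * rho2) * tex
        sub = frame[y0:y1, x0:x1]
        np.maximum(sub, np.where(inside, intensity, 0.0), out=sub)
        own = inside & (rho2 < best_rho2[y0:y1, x0:x1])
        best_rho2[y0:y1, x0:x1][own] = rho2[own]
        labels[y0:y1, x0:x1][own] = c.cid
    counts = np.bincount(labels.ravel(), minlength=1)
    sums_x = np.bincount(labels.ravel(), weights=np.tile(np.arange(w), h), minlength=1)
    sums_y = np.bincount(labels.ravel(), weights=np.repeat(np.arange(h), w), minlength=1)
    centroids = {}
    for c in cells:
        n = int(counts[c.cid]) if c.cid < counts.size else 0
        areas[c.cid] = n
        if n > 0:
            centroids[c.cid] = (sums_x[c.cid] / n, sums_y[c.cid] / n)
    return np.clip(frame, 0.0, 1.0).astype(np.float32), labels, areas, centroids


def _monolayer_mask(labels: np.ndarray, r_close_px: float) -> np.ndarray:
    """2-class monolayer view: union of cells closed with a mean-radius disk.

    The rendered monolayer has small intercellular gaps; a visually closed
    sheet is recovered by morphological closing.
    """
    r = max(1, int(round(r_close_px)))
    se = disk(r)
    # pad by replication so closing does not erode sheet regions touching
    # the image border
    padded = np.pad(labels > 0, r, mode="edge")
    closed = ndi.binary_closing(padded, structure=se)[r:-r, r:-r]
    return closed.astype(np.uint8)


def _true_edges(mask: np.ndarray, gap_center_px: float) -> np.ndarray:
    """Per-row x of the left/right leading edge from the 2-class mask."""
    h, w = mask.shape
    out = np.full((2, h), np.nan)
    cols = np.arange(w)
    for y in range(h):
        row = mask[y] > 0
        left = row & (cols < gap_center_px)
        right = row & (cols >= gap_center_px)
        if left.any():
            out[0, y] = cols[left].max()
        if right.any():
            out[1, y] = cols[right].min()
    for i in range(2):  # fill rare empty rows from neighbours
        s = pd.Series(out[i])
        out[i] = s.ffill().bfill().to_numpy()
    return out


def simulate_scene(cfg: SceneConfig) -> tuple[ImageSequence, GroundTruth]:
    """Simulate a scratch-assay sequence and its complete ground truth.

    Every cell superposes a directed component toward the gap centre and an
    isotropic Gaussian random walk.  The directed speed is the full
    (side-specific) edge speed for border cells and decays exponentially
    with depth behind the front for followers, so the sheet advances
    without tearing.  The random-walk component sigma is calibrated so the
    mean step magnitude equals ``v_inner_mm_h * dt`` (Rayleigh mean),
    making the tracked mean speed an unbiased estimate of ``v_inner_mm_h``
    wherever the directed component vanishes.  With a positive division
    rate cells divide stochastically (count never decreases).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r_mean_px = cfg.cell_radius_um_mean / cfg.pixel_size_um
    gap_half_px = cfg.gap_width_um / cfg.pixel_size_um / 2.0
    center = cfg.width_px / 2.0
    x_left, x_right = center - gap_half_px, center + gap_half_px

    cells, next_id = _place_monolayer(rng, cfg, 0.0, x_left, 0, r_mean_px, next_id=1)
    right_cells, next_id = _place_monolayer(rng, cfg, x_right, float(cfg.width_px), 1, r_mean_px, next_id)
    cells = cells + right_cells

    substrate = None
    if cfg.substrate_texture > 0:
        field = ndi.gaussian_filter(rng.standard_normal((cfg.height_px, cfg.width_px)), 3.0)
        substrate = cfg.substrate_texture * field / field.std()

    step_edge = mm_per_h_to_px_per_frame(cfg.v_edge_mm_h, cfg.pixel_size_um, cfg.dt_min)
    sigma_inner = mm_per_h_to_px_per_frame(cfg.v_inner_mm_h, cfg.pixel_size_um, cfg.dt_min) / np.sqrt(np.pi / 2.0)
    p_div = cfg.division_rate_per_h * cfg.dt_min / 60.0

    frames = []
    label_maps = []
    mono_masks = []
    edges = []
    records = []  # (frame, cid, x, y) before areas/velocities
    areas_all = []

    positions: list[dict[int, tuple[float, float]]] = []
    centroids_all = []
    for t in range(cfg.n_frames):
        frame, labels, areas, centroids = _render_frame(cells, cfg, substrate)
        frames.append(frame)
        label_maps.append(labels)
        mono = _monolayer_mask(labels, r_mean_px)
        mono_masks.append(mono)
        edges.append(_true_edges(mono, center))
        positions.append({c.cid: (c.x, c.y) for c in cells})
        areas_all.append(areas)
        centroids_all.append(centroids)

        if t == cfg.n_frames - 1:
            break
        # --- advance kinematics ---
        new_cells = []
        for c in cells:
            speed = step_edge * (1.0 + cfg.asymmetry if c.side == 0 else 1.0 - cfg.asymmetry)
            directed = c.drift * speed * (1.0 if c.side == 0 else -1.0)
            dx, dy = rng.normal(0.0, sigma_inner, 2)
            c.x += directed + dx
            c.y += dy
            # reflecting walls: a clamp would pile cells up at the image
            # border and systematically truncate their steps there
            margin = max(c.a, c.b)
            c.x = _reflect(c.x, margin, cfg.width_px - 1 - margin)
            c.y = _reflect(c.y, margin, cfg.height_px - 1 - margin)
            if cfg.deformation > 0:
                c.a = max(2.0, c.a * (1.0 + rng.normal(0.0, cfg.deformation)))
                c.b = max(2.0, c.b * (1.0 + rng.normal(0.0, cfg.deformation)))
            if p_div > 0 and rng.random() < p_div:
                ang = rng.uniform(0, 2 * np.pi)
                d = 1.6 * max(c.a, c.b)
                nx = float(np.clip(c.x + d * np.cos(ang), margin, cfg.width_px - 1 - margin))
                ny = float(np.clip(c.y + d * np.sin(ang), margin, cfg.height_px - 1 - margin))
                new_cells.append(
                    _Cell(next_id, nx, ny, c.a, c.b, rng.uniform(0, np.pi), c.side, c.border, c.drift, rng.random((_NTEX, _NTEX)))
                )
                next_id += 1
        cells.extend(new_cells)

    # --- assemble ground-truth table; centroids are the rendered-region
    # centroids (exactly consistent with the label maps), velocities the
    # clean kinematic forward differences of the continuous cell centres ---
    for t, pos in enumerate(positions):
        nxt = positions[t + 1] if t + 1 < len(positions) else None
        prv = positions[t - 1] if t > 0 else None
        for cid, (x, y) in pos.items():
            if cid not in centroids_all[t]:
                continue  # fully occluded cell: nothing rendered, no record
            if nxt is not None and cid in nxt:
                dxy = (nxt[cid][0] - x, nxt[cid][1] - y)
            elif prv is not None and cid in prv:
                dxy = (x - prv[cid][0], y - prv[cid][1])
            else:
                dxy = (0.0, 0.0)
            vx = px_per_frame_to_mm_per_h(dxy[0], cfg.pixel_size_um, cfg.dt_min)
            vy = px_per_frame_to_mm_per_h(dxy[1], cfg.pixel_size_um, cfg.dt_min)
            gx, gy = centroids_all[t][cid]
            records.append((t, cid, gx, gy, areas_all[t].get(cid, 0), vx, vy))

    cells_df = pd.DataFrame(records, columns=["frame", "cell_id", "x_px", "y_px", "area_px2", "vx_mm_h", "vy_mm_h"])
    seq = ImageSequence(np.stack(frames), cfg.pixel_size_um, cfg.dt_min, metadata={"seed": cfg.seed})
    gt = GroundTruth(
        cells=cells_df,
        label_maps=np.stack(label_maps),
        monolayer_masks=np.stack(mono_masks),
        edges=np.stack(edges),
        config=cfg,
    )
    return seq, gt


def add_gaussian_noise(seq: ImageSequence, mean: float = 0.0, variance: float = 0.01, seed: int = 0) -> ImageSequence:
    """Additive i.i.d. Gaussian noise, clipped back to [0, 1].

    Defaults (mean 0, variance 0.01) follow the classic parameterisation of
    the classic additive-Gaussian image distortion used in robustness tests.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0 and mean == 0:
        return ImageSequence(seq.frames.copy(), seq.pixel_size_um, seq.dt_min, dict(seq.metadata))
    rng = np.random.default_rng(seed)
    noisy = seq.frames + rng.normal(mean, np.sqrt(variance), seq.frames.shape)
    return ImageSequence(
        np.clip(noisy, 0.0, 1.0).astype(np.float32),
        seq.pixel_size_um,
        seq.dt_min,
        {**seq.metadata, "noise_variance": variance},
    )


def render_labels(gt: GroundTruth, border_width_px: int = 2) -> np.ndarray:
    """3-class label masks (background=0, cell=1, border=2) from ground truth.

    The border class is the inner morphological-gradient ring of each cell:
    cell pixels removed by erosion with a disk of the given width.  Because
    pixel ownership is exclusive, the class-1 interiors of touching cells
    are always separated by class-2 pixels.
    """
    if border_width_px < 1:
        raise ValueError("border_width_px must be >= 1")
    se = disk(border_width_px)
    out = np.zeros(gt.label_maps.shape, dtype=np.uint8)
    for t in range(gt.label_maps.shape[0]):
        labels = gt.label_maps[t]
        mask3 = np.where(labels > 0, np.uint8(2), np.uint8(0))
        objs = ndi.find_objects(labels)
        for i, sl in enumerate(objs):
            if sl is None:
                continue
            cid = i + 1
            pad = border_width_px + 1
            y0 = max(sl[0].start - pad, 0)
            y1 = min(sl[0].stop + pad, labels.shape[0])
            x0 = max(sl[1].start - pad, 0)
            x1 = min(sl[1].stop + pad, labels.shape[1])
            region = labels[y0:y1, x0:x1] == cid
            interior = ndi.binary_erosion(region, structure=se)
            sub = mask3[y0:y1, x0:x1]
            sub[interior] = 1
        out[t] = mask3
    return out
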