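"""Adaptive local-mean threshold segmentation (the conventional baseline).

A pixel is foreground when its value exceeds the mean grey value of a
rectangular neighborhood scaled by a sensitivity-dependent factor.  With
``sensitivity`` s and bright cells on a dark background the rule is

    value > local_mean * 2 * (1 - s)

so s = 0.5 reduces to "above the local mean" and raising s admits more
pixels (for ``dark_cells`` the comparison is mirrored:
value < local_mean * 2 * s).  Holes in detected cells are then filled and
components below a minimum plausible cell area removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from sklearn.base import BaseEstimator

from .cellscale import CellDetection
from .core import remove_small_components

__all__ = [
    "AdaptiveConfig",
    "AdaptiveSegmenter",
    "local_mean",
    "adaptive_threshold",
    "mask_to_detections",
]


@dataclass
class AdaptiveConfig:
    """Neighborhood, sensitivity and cleanup settings.

    The default 161 x 121 px neighborhood and sensitivity around 0.5-0.7
    are the ranges that work well for endothelial monolayer images.
    """

    window_w_px: int = 161
    window_h_px: int = 121
    sensitivity: float = 0.6
    polarity: str = "bright_cells"
    min_cell_area_px2: int = 50
    fill_holes: bool = True

    def validate(self) -> None:
        for s in (self.window_w_px, self.window_h_px):
            if s < 3 or s % 2 == 0:
                raise ValueError("window dimensions must be odd and >= 3")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.polarity not in ("bright_cells", "dark_cells"):
            raise ValueError("polarity must be 'bright_cells' or 'dark_cells'")
        if self.min_cell_area_px2 < 0:
            raise ValueError("min_cell_area_px2 must be non-negative")


def local_mean(frame: np.ndarray, cfg: AdaptiveConfig) -> np.ndarray:
    """Per-pixel mean over the window centred at the pixel.

    Borders are handled by reflection so that the mean field is unbiased at
    the image edges.
    """
    cfg.validate()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite values")
    if cfg.window_h_px > frame.shape[0] or cfg.window_w_px > frame.shape[1]:
        raise ValueError("window larger than image")
    return ndi.uniform_filter(frame, size=(cfg.window_h_px, cfg.window_w_px), mode="reflect")


def adaptive_threshold(frame: np.ndarray, cfg: AdaptiveConfig | None = None) -> np.ndarray:
    """Binary foreground mask by the sensitivity-scaled local-mean rule."""
    cfg = cfg or AdaptiveConfig()
    mean = local_mean(frame, cfg)
    frame = np.asarray(frame, dtype=float)
    if cfg.polarity == "bright_cells":
        mask = frame > mean * (2.0 * (1.0 - cfg.sensitivity))
    else:
        mask = frame < mean * (2.0 * cfg.sensitivity)
    if cfg.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if cfg.min_cell_area_px2 > 1:
        mask = remove_small_components(mask, cfg.min_cell_area_px2)
    return mask


def mask_to_detections(mask: np.ndarray, frame_idx: int = 0) -> list[CellDetection]:
    """8-connected components of a binary mask as cell detections.

    Ids follow the raster order of each component's first (topmost, then
    leftmost) pixel, starting at 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    lab = label(mask, connectivity=2)
    dets = []
    for i, rp in enumerate(regionprops(lab)):
        cy, cx = rp.centroid
        dets.append(CellDetection(frame=frame_idx, id=i, centroid_x_px=float(cx), centroid_y_px=float(cy), area_px2=float(rp.area)))
    return dets


class AdaptiveSegmenter(BaseEstimator):
    """Sklearn-style wrapper around the adaptive-threshold pipeline.

    The method has no trainable state; :meth:`fit` only validates the
    parameters so the estimator composes with sklearn tooling.
    """

    def __init__(
        self,
        window_w_px: int = 161,
        window_h_px: int = 121,
        sensitivity: float = 0.6,
        polarity: str = "bright_cells",
        min_cell_area_px2: int = 50,
        fill_holes: bool = True,
    ):
        self.window_w_px = window_w_px
        self.window_h_px = window_h_px
        self.sensitivity = sensitivity
        self.polarity = polarity
        self.min_cell_area_px2 = min_cell_area_px2
        self.fill_holes = fill_holes

    def _config(self) -> AdaptiveConfig:
        return AdaptiveConfig(
            window_w_px=self.window_w_px,
            window_h_px=self.window_h_px,
            sensitivity=self.sensitivity,
            polarity=self.polarity,
            min_cell_area_px2=self.min_cell_area_px2,
            fill_holes=self.fill_holes,
        )

    def fit(self, X=None, y=None) -> "AdaptiveSegmenter":
        self._config().validate()
        self.fitted_ = True
        return self

    def predict(self, frame: np.ndarray) -> np.ndarray:
        """Binary cell mask for one frame."""
        return adaptive_threshold(frame, self._config())

    def detect(self, frame: np.ndarray, frame_idx: int = 0) -> list[CellDetection]:
        """Segment one frame and return its cell detections."""
        return mask_to_detections(self.predict(frame), frame_idx)
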