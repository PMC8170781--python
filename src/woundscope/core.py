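"""Shared containers and unit conversions for wound-healing image analysis.

Conventions used throughout the package: pixel coordinates are 0-based with
``x`` the column index (rightward) and ``y`` the row index (downward); the
scratch gap runs vertically, i.e. perpendicular to ``x``.  Physical lengths
are micrometres per pixel, times are minutes per frame, and speeds are
reported in mm/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageSequence",
    "px_per_frame_to_mm_per_h",
    "mm_per_h_to_px_per_frame",
    "remove_small_components",
]


def remove_small_components(mask: np.ndarray, min_area_px2: int, connectivity: int = 2) -> np.ndarray:
    """Drop 8-connected (or 4-connected) foreground components smaller than
    ``min_area_px2`` pixels."""
    from scipy import ndimage as ndi

    mask = np.asarray(mask).astype(bool)
    if min_area_px2 <= 1 or not mask.any():
        return mask
    structure = np.ones((3, 3)) if connectivity == 2 else None
    lab, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area_px2
    keep[0] = False
    return keep[lab]


def px_per_frame_to_mm_per_h(d_px: float, pixel_size_um: float, dt_min: float) -> float:
    """Convert a per-frame pixel displacement to a speed in mm/h.

    A maximum linking radius of 25 px at 1.4 um/px and a 15 min frame
    interval corresponds to 25 * 1.4e-3 mm / 0.25 h = 0.14 mm/h.
    """
    return d_px * (pixel_size_um / 1000.0) / (dt_min / 60.0)


def mm_per_h_to_px_per_frame(v_mm_h: float, pixel_size_um: float, dt_min: float) -> float:
    """Inverse of :func:`px_per_frame_to_mm_per_h`."""
    return v_mm_h * (dt_min / 60.0) / (pixel_size_um / 1000.0)


@dataclass
class ImageSequence:
    """An ordered stack of grayscale frames with physical calibration.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W), float in [0, 1]
        The image data.
    pixel_size_um : float
        Edge length of one pixel in micrometres.
    dt_min : float
        Time between consecutive frames in minutes.
    """

    frames: np.ndarray
    pixel_size_um: float = 1.4
    dt_min: float = 15.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size_um <= 0 or self.dt_min <= 0:
            raise ValueError("pixel_size_um and dt_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def width_mm(self) -> float:
        return self.frames.shape[2] * self.pixel_size_um / 1000.0

    @property
    def height_mm(self) -> float:
        return self.frames.shape[1] * self.pixel_size_um / 1000.0

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]
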