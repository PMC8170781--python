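"""Paired image/label augmentation: skew, rotation, translation, brightness.

Geometric transforms are applied identically to the image (bilinear) and
the label map (nearest neighbor, so label values never leave the original
class set); brightness scaling touches the image only.  Square inputs
rotated by exact multiples of 90 degrees (without skew or fractional
translation) take a lossless integer path.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform, warp

__all__ = ["apply_affine", "augment"]


def apply_affine(
    image: np.ndarray,
    label: np.ndarray,
    angle_deg: float = 0.0,
    skew_deg: float = 0.0,
    tx_px: float = 0.0,
    ty_px: float = 0.0,
    brightness: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One augmentation: rotation about the image centre, shear, translation
    and a multiplicative brightness change (image clipped back to [0, 1])."""
    image = np.asarray(image, dtype=np.float32)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ValueError("image and label must be aligned")
    exact_rot = (
        angle_deg % 90 == 0
        and skew_deg == 0
        and float(tx_px).is_integer()
        and float(ty_px).is_integer()
        and image.shape[0] == image.shape[1]
    )
    if exact_rot:
        k = int(angle_deg // 90) % 4
        img = np.rot90(image, k)
        lab = np.rot90(label, k)
        if tx_px or ty_px:
            img = np.roll(img, (int(ty_px), int(tx_px)), axis=(0, 1))
            lab = np.roll(lab, (int(ty_px), int(tx_px)), axis=(0, 1))
        img = img.copy()
        lab = lab.copy()
    else:
        h, w = image.shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=np.deg2rad(angle_deg), shear=np.deg2rad(skew_deg))
            + AffineTransform(translation=center + [tx_px, ty_px])
        )
        img = warp(image, tf.inverse, order=1, mode="reflect", preserve_range=True).astype(np.float32)
        lab = warp(label.astype(float), tf.inverse, order=0, mode="reflect", preserve_range=True).astype(label.dtype)
    if brightness:
        img = np.clip(img * (1.0 + brightness), 0.0, 1.0)
    return img, lab


def augment(
    image: np.ndarray,
    label: np.ndarray,
    n: int,
    seed: int = 0,
    max_rotation_deg: float = 180.0,
    max_skew_deg: float = 10.0,
    max_translate_frac: float = 0.1,
    max_brightness: float = 0.2,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` random augmented pairs from one training pair."""
    rng = np.random.default_rng(seed)
    out = []
    h, w = np.asarray(image).shape
    for _ in range(n):
        out.append(
            apply_affine(
                image,
                label,
                angle_deg=rng.uniform(-max_rotation_deg, max_rotation_deg),
                skew_deg=rng.uniform(-max_skew_deg, max_skew_deg),
                tx_px=rng.uniform(-max_translate_frac, max_translate_frac) * w,
                ty_px=rng.uniform(-max_translate_frac, max_translate_frac) * h,
                brightness=rng.uniform(-max_brightness, max_brightness),
            )
        )
    return out
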