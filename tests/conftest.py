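"""Shared fixtures: synthetic scenes and the trained mini U-net.

The U-net fixture trains once per session (208 patches of 128 x 128, half
of them Gaussian-noise distorted, 8 epochs) and is shared between the
segmentation-quality and noise-robustness tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import woundscope as ws
from woundscope.cellscale import CellDetection
from woundscope.unet import UNetSegmenter


def gt_detections(gt: ws.GroundTruth, t: int) -> list[CellDetection]:
    """Ground-truth cell records of frame t as detections."""
    f = gt.frame_cells(t)
    return [
        CellDetection(t, int(r.cell_id), float(r.x_px), float(r.y_px), float(r.area_px2))
        for r in f.itertuples()
    ]


def training_patches(n_scenes: int = 13, patch: int = 128, noise_every_other: bool = True):
    """128 x 128 labelled patches tiled from small two-monolayer scenes;
    every other scene is distorted with variance-0.01 Gaussian noise so the
    segmenter learns to ignore it."""
    imgs, labs = [], []
    for s in range(n_scenes):
        cfg = ws.SceneConfig(width_px=512, height_px=256, n_frames=2, seed=200 + s, gap_width_um=250)
        seq, gt = ws.simulate_scene(cfg)
        if noise_every_other and s % 2 == 1:
            seq = ws.add_gaussian_noise(seq, 0.0, 0.01, seed=s + 5000)
        m3 = gt.class_masks(2)
        for t in range(seq.n_frames):
            for y0 in range(0, cfg.height_px, patch):
                for x0 in range(0, cfg.width_px, patch):
                    imgs.append(seq.frames[t][y0 : y0 + patch, x0 : x0 + patch])
                    labs.append(m3[t][y0 : y0 + patch, x0 : x0 + patch])
    return imgs, labs


@pytest.fixture(scope="session")
def trained_icd() -> UNetSegmenter:
    imgs, labs = training_patches()
    assert len(imgs) >= 200
    est = UNetSegmenter(n_classes=3, n_stages=3, base_features=8, epochs=8, batch_size=30, seed=0)
    est.fit(imgs, labs)
    return est


@pytest.fixture(scope="session")
def small_scene():
    """A compact default scene with motion, reused by read-only tests."""
    cfg = ws.SceneConfig(n_frames=6, seed=3)
    seq, gt = ws.simulate_scene(cfg)
    return cfg, seq, gt
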