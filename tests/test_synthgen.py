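"""Scene generator: determinism, ground-truth consistency, kinematics."""

import numpy as np
import pytest
import scipy.ndimage as ndi

import woundscope as ws


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ws.SceneConfig(width_px=300, gap_width_um=500).validate()  # gap wider than image
    with pytest.raises(ValueError):
        ws.SceneConfig(n_frames=0).validate()
    with pytest.raises(ValueError):
        ws.SceneConfig(asymmetry=1.5).validate()


def test_identical_seed_identical_scene(small_scene):
    cfg, seq, gt = small_scene
    seq2, gt2 = ws.simulate_scene(ws.SceneConfig(**{**cfg.__dict__}))
    assert np.array_equal(seq.frames, seq2.frames)
    assert gt.cells.equals(gt2.cells)
    assert np.array_equal(gt.label_maps, gt2.label_maps)


def test_frames_are_unit_floats(small_scene):
    _, seq, _ = small_scene
    assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0


def test_cell_count_constant_without_division(small_scene):
    cfg, _, gt = small_scene
    counts = [gt.n_cells(t) for t in range(cfg.n_frames)]
    assert len(set(counts)) == 1


def test_cell_count_nondecreasing_with_division():
    cfg = ws.SceneConfig(width_px=512, height_px=256, n_frames=5, seed=9, gap_width_um=250,
                         division_rate_per_h=0.4)
    _, gt = ws.simulate_scene(cfg)
    counts = [gt.n_cells(t) for t in range(5)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))
    assert counts[-1] > counts[0]  # at this rate some division must occur


def test_ground_truth_centroids_match_rendered_regions(small_scene):
    cfg, _, gt = small_scene
    for t in (0, cfg.n_frames - 1):
        lab = gt.label_maps[t]
        f = gt.frame_cells(t)
        coms = ndi.center_of_mass(lab > 0, lab, f.cell_id.to_numpy())
        err = max(np.hypot(c[1] - x, c[0] - y) for c, (x, y) in zip(coms, zip(f.x_px, f.y_px)))
        assert err < 1.0


def test_one_record_per_rendered_cell(small_scene):
    cfg, _, gt = small_scene
    for t in (0, cfg.n_frames - 1):
        ids_in_map = set(np.unique(gt.label_maps[t])) - {0}
        ids_in_table = set(gt.frame_cells(t).cell_id)
        assert ids_in_map == ids_in_table


def test_static_scene_has_zero_motion():
    cfg = ws.SceneConfig(width_px=512, height_px=256, n_frames=5, seed=4, gap_width_um=250,
                         v_edge_mm_h=0.0, v_inner_mm_h=0.0)
    _, gt = ws.simulate_scene(cfg)
    piv = gt.cells.pivot_table(index="cell_id", columns="frame", values=["x_px", "y_px"])
    assert np.allclose(piv["x_px"].std(axis=1), 0)
    assert np.allclose(piv["y_px"].std(axis=1), 0)
    assert np.allclose(gt.cells[["vx_mm_h", "vy_mm_h"]], 0)


def test_border_cell_displacement_matches_unit_conversion():
    # 0.03 mm/h at dt=15 min and 1.4 um/px must advance 0.03*0.25/0.0014
    # = 5.357 px/frame; with the random walk switched off the ground-truth
    # velocity is exact and the rendered centroids track it closely.
    cfg = ws.SceneConfig(n_frames=2, seed=5, v_edge_mm_h=0.03, v_inner_mm_h=0.0)
    _, gt = ws.simulate_scene(cfg)
    expected_px = 0.03 * (15 / 60) / (1.4 / 1000)
    assert expected_px == pytest.approx(5.357, abs=0.001)
    vmax = gt.cells.vx_mm_h.abs().max()
    assert vmax == pytest.approx(0.03, rel=1e-9)  # border cells, exact
    border = gt.frame_cells(0).merge(gt.frame_cells(1), on="cell_id", suffixes=("", "_1"))
    border = border[np.isclose(border.vx_mm_h.abs(), 0.03)]
    disp = np.hypot(border.x_px_1 - border.x_px, border.y_px_1 - border.y_px)
    assert disp.mean() == pytest.approx(expected_px, rel=0.02)


def test_pixel_size_scaling_halves_displacements():
    # same physical speeds, doubled pixel size -> half the pixel steps
    base = dict(width_px=512, height_px=256, n_frames=3, seed=8, gap_width_um=250,
                v_edge_mm_h=0.03, v_inner_mm_h=0.0)
    _, gt1 = ws.simulate_scene(ws.SceneConfig(**base, pixel_size_um=1.4))
    _, gt2 = ws.simulate_scene(ws.SceneConfig(**base, pixel_size_um=2.8))
    d1 = ws.mm_per_h_to_px_per_frame(0.03, 1.4, 15)
    d2 = ws.mm_per_h_to_px_per_frame(0.03, 2.8, 15)
    assert d1 == pytest.approx(2 * d2)
    for gt, d in ((gt1, d1), (gt2, d2)):
        m = gt.frame_cells(0).merge(gt.frame_cells(1), on="cell_id", suffixes=("", "_1"))
        m = m[np.isclose(m.vx_mm_h.abs(), 0.03)]
        assert np.hypot(m.x_px_1 - m.x_px, m.y_px_1 - m.y_px).mean() == pytest.approx(d, rel=0.02)


def test_monolayer_mask_covers_cells_and_spares_gap(small_scene):
    cfg, _, gt = small_scene
    mono = gt.monolayer_masks[0]
    assert (mono[gt.label_maps[0] > 0] == 1).all()  # cells inside the sheet
    gap_center = slice(cfg.width_px // 2 - 50, cfg.width_px // 2 + 50)
    assert mono[:, gap_center].sum() == 0  # central gap band is empty


class TestGaussianNoise:
    def test_zero_variance_is_identity(self, small_scene):
        _, seq, _ = small_scene
        out = ws.add_gaussian_noise(seq, 0.0, 0.0, seed=1)
        assert np.array_equal(out.frames, seq.frames)

    def test_negative_variance_rejected(self, small_scene):
        _, seq, _ = small_scene
        with pytest.raises(ValueError):
            ws.add_gaussian_noise(seq, 0.0, -0.1, seed=1)

    def test_sample_variance_matches_requested(self):
        flat = ws.ImageSequence(np.full((1, 512, 512), 0.5, dtype=np.float32))
        out = ws.add_gaussian_noise(flat, 0.0, 0.01, seed=2)
        # no clipping at 0.5 +- ~5 sigma, so the moments are clean
        assert np.var(out.frames[0] - 0.5) == pytest.approx(0.01, rel=0.05)

    def test_same_seed_same_noise(self, small_scene):
        _, seq, _ = small_scene
        a = ws.add_gaussian_noise(seq, 0.0, 0.01, seed=3)
        b = ws.add_gaussian_noise(seq, 0.0, 0.01, seed=3)
        assert np.array_equal(a.frames, b.frames)


class TestRenderLabels:
    def test_border_ring_area_matches_disk_difference(self):
        # one circular cell: the class-2 ring must equal the brute-force
        # set difference between the disk and its erosion
        from scipy.ndimage import binary_erosion
        from skimage.morphology import disk as disk_se

        lab = np.zeros((1, 64, 64), dtype=np.int32)
        yy, xx = np.mgrid[0:64, 0:64]
        region = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2
        lab[0][region] = 1
        gt = ws.GroundTruth(
            cells=None, label_maps=lab, monolayer_masks=lab.astype(np.uint8), edges=None,
            config=ws.SceneConfig(),
        )
        m3 = ws.render_labels(gt, border_width_px=2)
        ring = m3[0] == 2
        expected = region & ~binary_erosion(region, structure=disk_se(2))
        assert np.array_equal(ring, expected)
        assert ring.sum() == pytest.approx(2 * np.pi * 10 * 2, rel=0.25)  # ~ perimeter * width

    def test_empty_frame_all_background(self):
        lab = np.zeros((1, 32, 32), dtype=np.int32)
        gt = ws.GroundTruth(cells=None, label_maps=lab, monolayer_masks=lab.astype(np.uint8),
                            edges=None, config=ws.SceneConfig())
        assert (ws.render_labels(gt, 2) == 0).all()

    def test_touching_cells_keep_distinct_interiors(self):
        lab = np.zeros((1, 40, 80), dtype=np.int32)
        yy, xx = np.mgrid[0:40, 0:80]
        lab[0][(yy - 20) ** 2 + (xx - 25) ** 2 <= 100] = 1
        lab[0][((yy - 20) ** 2 + (xx - 46) ** 2 <= 100) & (lab[0] == 0)] = 2
        gt = ws.GroundTruth(cells=None, label_maps=lab, monolayer_masks=(lab > 0).astype(np.uint8),
                            edges=None, config=ws.SceneConfig())
        m3 = ws.render_labels(gt, 2)
        import scipy.ndimage as ndi2

        comp, n = ndi2.label(m3[0] == 1, structure=np.ones((3, 3)))
        assert n == 2

    def test_scene_class_masks_partition(self, small_scene):
        _, _, gt = small_scene
        m3 = gt.class_masks(2)
        assert set(np.unique(m3)) <= {0, 1, 2}
        # cell+border pixels exactly cover the labelled regions
        assert np.array_equal(m3[0] > 0, gt.label_maps[0] > 0)
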