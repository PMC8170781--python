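"""Leading-edge reconstruction, protrusion length, gap-closure series."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import woundscope as ws


def straight_phantom(h=200, w=400, left_end=100, right_start=300):
    mask = np.zeros((h, w), bool)
    mask[:, : left_end + 1] = True
    mask[:, right_start:] = True
    return mask


@pytest.fixture(scope="module")
def textured_phantom():
    """Grayscale phantom: smoothly textured monolayers, flat dark gap."""
    rng = np.random.default_rng(0)
    h, w = 200, 400
    img = np.full((h, w), 0.1)
    tex = gaussian_filter(rng.random((h, w)), 1.5)
    tex = 0.4 + 0.5 * (tex - tex.min()) / (tex.max() - tex.min())
    img[:, :101] = tex[:, :101]
    img[:, 300:] = tex[:, 300:]
    return img


class TestStraightEdgeGeometry:
    def test_mean_position_and_length_exact(self):
        left, right, _ = ws.edge_from_idsd(straight_phantom(), pixel_size_um=1.4)
        assert left.mean_x_mm == pytest.approx(100 * 1.4 / 1000, abs=1e-12)
        assert right.mean_x_mm == pytest.approx(300 * 1.4 / 1000, abs=1e-12)
        assert left.length_mm == pytest.approx(200 * 1.4 / 1000, abs=1e-12)
        assert right.length_mm == pytest.approx(200 * 1.4 / 1000, abs=1e-12)

    def test_cell_route_is_identity_on_halfplanes(self):
        left, right, _ = ws.edge_from_cells(straight_phantom(), 15, 1.4)
        assert left.mean_x_mm == pytest.approx(0.14, abs=1e-12)
        assert left.length_mm == pytest.approx(0.28, abs=1e-12)
        assert right.mean_x_mm == pytest.approx(0.42, abs=1e-12)

    def test_left_always_left_of_right(self):
        left, right, _ = ws.edge_from_idsd(straight_phantom(), 1.4)
        assert left.mean_x_mm < right.mean_x_mm


class TestSinusoidalEdge:
    def test_length_matches_analytic_arc_length(self):
        h, w = 200, 400
        ys = np.arange(h)
        xs = 100 + 20 * np.sin(2 * np.pi * ys / 100.0)
        mask = np.zeros((h, w), bool)
        for y in ys:
            mask[y, : int(round(xs[y])) + 1] = True
        mask[:, 300:] = True
        left, _, _ = ws.edge_from_idsd(mask, pixel_size_um=1.4)
        yy = np.linspace(0, h, 20001)
        dx = 20 * (2 * np.pi / 100) * np.cos(2 * np.pi * yy / 100.0)
        arc_px = np.trapezoid(np.sqrt(1 + dx**2), yy)
        assert left.length_mm * 1000 / 1.4 == pytest.approx(arc_px, rel=0.05)

    def test_perturbed_edge_never_shorter_than_straight(self):
        mask = straight_phantom()
        bumped = mask.copy()
        bumped[80:120, 101:115] = True  # protrusion on the left front
        l0, _, _ = ws.edge_from_idsd(mask, 1.4)
        l1, _, _ = ws.edge_from_idsd(bumped, 1.4)
        assert l1.length_mm >= l0.length_mm


class TestArtifactRobustness:
    def debris_mask(self):
        mask = straight_phantom()
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        for cx, cy in [(150, 30), (200, 100), (250, 170), (180, 60), (220, 140)]:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 9
        return mask

    def test_cell_route_ignores_debris(self):
        clean_l, clean_r, _ = ws.edge_from_cells(straight_phantom(), 15, 1.4)
        l, r, _ = ws.edge_from_cells(self.debris_mask(), 15, 1.4)
        assert l.mean_x_mm == clean_l.mean_x_mm and l.length_mm == clean_l.length_mm
        assert r.mean_x_mm == clean_r.mean_x_mm and r.length_mm == clean_r.length_mm

    def test_direct_route_ignores_hole_in_monolayer(self):
        mask = straight_phantom()
        holed = mask.copy()
        holed[90:110, 30:50] = False  # false "gap" inside the left sheet
        l0, r0, _ = ws.edge_from_idsd(mask, 1.4)
        l1, r1, _ = ws.edge_from_idsd(holed, 1.4)
        assert l1.mean_x_mm == l0.mean_x_mm and l1.length_mm == l0.length_mm

    def test_canny_route_frays_with_debris(self, textured_phantom):
        clean_l, clean_r, _ = ws.edge_from_canny(textured_phantom, pixel_size_um=1.4)
        img = textured_phantom.copy()
        yy, xx = np.mgrid[0:200, 0:400]
        for cx, cy in [(150, 30), (200, 100), (250, 170)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 16] = 0.8
        l, r, _ = ws.edge_from_canny(img, pixel_size_um=1.4)
        assert l.length_mm + r.length_mm > clean_l.length_mm + clean_r.length_mm


class TestCannyRoute:
    def test_gap_area_close_to_truth(self, textured_phantom):
        _, _, mono = ws.edge_from_canny(textured_phantom, pixel_size_um=1.4)
        true_gap = 200 * 199  # columns 101..299
        assert (~mono).sum() == pytest.approx(true_gap, rel=0.1)

    def test_mean_position_close_and_length_frayed(self, textured_phantom):
        left, right, _ = ws.edge_from_canny(textured_phantom, pixel_size_um=1.4)
        assert left.mean_x_mm == pytest.approx(100 * 1.4 / 1000, abs=2 * 1.4 / 1000)
        assert right.mean_x_mm == pytest.approx(300 * 1.4 / 1000, abs=2 * 1.4 / 1000)
        assert left.length_mm >= 200 * 1.4 / 1000  # frays, never shorter

    def test_constant_frame_raises_no_edge(self):
        with pytest.raises(ws.NoEdgeError):
            ws.edge_from_canny(np.full((100, 100), 0.5))


class TestClosureSignal:
    def test_single_monolayer_signals_closure(self):
        mask = np.ones((50, 80), bool)
        with pytest.raises(ws.GapClosedError):
            ws.edge_from_idsd(mask, 1.4)
        with pytest.raises(ws.GapClosedError):
            ws.edge_from_cells(mask, 5, 1.4)


class TestEdgeTimeSeries:
    def pair(self, left_x, right_x):
        mask = straight_phantom(left_end=left_x, right_start=right_x)
        left, right, _ = ws.edge_from_idsd(mask, 1.4)
        return left, right

    def test_static_series_constant(self):
        pairs = [self.pair(100, 300)] * 4
        series = ws.edge_timeseries(pairs, 15.0)
        assert np.allclose(series.gap_width_mm, series.gap_width_mm[0])
        assert series.closure_time_min is None

    def test_closure_time_from_first_closed_frame(self):
        pairs = [self.pair(100, 300), self.pair(150, 250), None, None]
        series = ws.edge_timeseries(pairs, 15.0)
        assert series.closure_time_min == 2 * 15.0
        assert series.gap_width_mm[1] < series.gap_width_mm[0]

    def test_asymmetric_scene_upstream_advances_faster(self):
        cfg = ws.SceneConfig(n_frames=5, seed=13, v_edge_mm_h=0.05, v_inner_mm_h=0.0, asymmetry=0.6)
        _, gt = ws.simulate_scene(cfg)
        pairs = []
        for t in range(cfg.n_frames):
            left, right, _ = ws.edge_from_idsd(gt.monolayer_masks[t] > 0, cfg.pixel_size_um, frame=t)
            pairs.append((left, right))
        s = ws.edge_timeseries(pairs, cfg.dt_min)
        adv_left = s.mean_x_mm["left"][-1] - s.mean_x_mm["left"][0]
        adv_right = s.mean_x_mm["right"][0] - s.mean_x_mm["right"][-1]
        assert adv_left > adv_right > 0


class TestRelativeErrorSeries:
    def make_series(self, lengths, positions):
        T = len(lengths)
        return ws.EdgeTimeSeries(
            dt_min=15.0,
            length_mm={"left": np.array(lengths), "right": np.array(lengths)},
            mean_x_mm={"left": np.array(positions), "right": np.array(positions) + 0.3},
            gap_width_mm=np.full(T, 0.3),
        )

    def test_identical_series_zero_error(self):
        ref = self.make_series([1.0, 1.1], [0.1, 0.12])
        out = ws.relative_error_series(ref, ref)
        assert out["length_mean"] == 0.0 and out["mean_x_mean"] == 0.0

    def test_twenty_percent_single_frame(self):
        ref = self.make_series([1.0], [0.1])
        cand = self.make_series([1.2], [0.1])
        out = ws.relative_error_series(cand, ref)
        assert out["length_left_mean"] == pytest.approx(0.2)

    def test_mean_of_mixed_errors(self):
        ref = self.make_series([1.0, 1.0], [0.1, 0.1])
        cand = self.make_series([1.1, 0.9], [0.1, 0.1])
        out = ws.relative_error_series(cand, ref)
        assert out["length_left_mean"] == pytest.approx(0.1)

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError):
            ws.relative_error_series(self.make_series([1.0], [0.1]), self.make_series([1.0, 1.0], [0.1, 0.1]))
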