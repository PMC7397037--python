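"""Spot detection, window placement, and density arithmetic."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from cgdist.errors import GeometryError, ResolutionError, ValidationError
from cgdist.image import ConfocalImage
from cgdist.simulate import SurfaceSimConfig, render_spots, simulate_surface
from cgdist.spots import (
    SpotSet,
    Window,
    detect_spots,
    measure_density,
    place_density_windows,
)


def make_image(pixels, ps=0.1):
    return ConfocalImage(np.clip(pixels, 0, None), ps)


class TestDetectSpots:
    def test_single_bright_spot_found_within_one_pixel(self):
        px = render_spots((128, 128), np.array([[60.3, 71.7]]), sigma_px=1.5, amplitude=100.0)
        img = make_image(px + 2.0)
        ss = detect_spots(img, None, scales=[0.15], response_threshold=10.0)
        assert len(ss) == 1
        assert np.hypot(ss.centers_px[0, 0] - 60.3, ss.centers_px[0, 1] - 71.7) <= 1.0

    def test_background_noise_below_5sd_threshold_yields_nothing(self):
        """Threshold at 5x the response noise SD (measured on the same fixed
        noise field by an oracle pass of the LoG filter) keeps zero
        detections."""
        rng = np.random.default_rng(12)
        noise = rng.normal(20.0, 4.0, (256, 256))
        img = make_image(noise)
        sigma_px = 0.15 / img.pixel_size
        resp = -(sigma_px**2) * ndimage.gaussian_laplace(img.pixels.astype(float), sigma_px)
        thr = 5.0 * resp.std()
        ss = detect_spots(img, None, scales=[0.15], response_threshold=thr)
        assert len(ss) == 0

    def test_recall_and_precision_on_separated_spots(self):
        """50 well-separated spots at SNR 12: recall and precision >= 0.95
        against ground truth under greedy matching at 2 px."""
        rng = np.random.default_rng(5)
        grid = np.array([(r, c) for r in range(5, 100, 14) for c in range(5, 100, 14)])
        jitter = rng.uniform(-2, 2, grid.shape)
        centers = (grid[:50] * 5 + 30 + jitter[:50]).astype(float)
        px = render_spots((600, 600), centers, sigma_px=1.5, amplitude=60.0)
        px += rng.normal(5.0, 5.0, px.shape)
        img = make_image(px)
        ss = detect_spots(img, None, scales=[0.12, 0.15, 0.18], response_threshold=11.0)
        # brute-force greedy bipartite matching at 2 px
        det = list(map(tuple, ss.centers_px))
        unmatched = set(range(len(centers)))
        tp = 0
        for d in det:
            best, best_j = None, None
            for j in unmatched:
                dist = np.hypot(d[0] - centers[j][0], d[1] - centers[j][1])
                if dist <= 2.0 and (best is None or dist < best):
                    best, best_j = dist, j
            if best_j is not None:
                unmatched.discard(best_j)
                tp += 1
        assert tp / len(centers) >= 0.95  # recall
        assert tp / len(det) >= 0.95  # precision

    def test_scale_below_pixel_is_resolution_error(self):
        img = make_image(np.ones((64, 64)), ps=0.3)
        with pytest.raises(ResolutionError):
            detect_spots(img, None, scales=[0.2], response_threshold=5.0)

    def test_scale_outside_granule_range_rejected(self):
        img = make_image(np.ones((64, 64)), ps=0.1)
        with pytest.raises(ValidationError):
            detect_spots(img, None, scales=[1.5], response_threshold=5.0)

    def test_detections_respect_mask(self):
        px = render_spots(
            (128, 128), np.array([[30.0, 30.0], [90.0, 90.0]]), sigma_px=1.5, amplitude=100.0
        )
        img = make_image(px + 2)
        mask = np.zeros((128, 128), bool)
        mask[:64, :64] = True
        ss = detect_spots(img, mask, scales=[0.15], response_threshold=10.0)
        assert len(ss) == 1
        assert ss.centers_px[0, 0] < 64

    def test_nms_enforces_min_separation(self):
        cfg = SurfaceSimConfig(
            image_size=300, pixel_size=0.1, target_density=80.0, granule_sigma=0.12,
            granule_amplitude=80.0, background=2.0, noise_model="none", noise_sd=0.0, seed=3,
        )
        img, _ = simulate_surface(cfg)
        ss = detect_spots(img, None, scales=[0.12], response_threshold=10.0)
        assert len(ss) > 50
        min_sep_px = np.sqrt(2) * 0.12 / 0.1
        from scipy.spatial import cKDTree

        d, _ = cKDTree(ss.centers_px).query(ss.centers_px, k=2)
        assert d[:, 1].min() >= min_sep_px - 1e-9

    def test_deterministic_for_fixed_input(self):
        cfg = SurfaceSimConfig(
            image_size=200, pixel_size=0.1, target_density=40.0, granule_sigma=0.12,
            granule_amplitude=60.0, background=5.0, noise_model="gaussian", noise_sd=6.0, seed=9,
        )
        img, _ = simulate_surface(cfg)
        a = detect_spots(img, None, scales=[0.1, 0.12], response_threshold=11.0)
        b = detect_spots(img, None, scales=[0.1, 0.12], response_threshold=11.0)
        np.testing.assert_array_equal(a.centers_px, b.centers_px)


class TestWindows:
    def test_three_disjoint_windows_fit_surface_field(self):
        region = np.ones((1000, 1000), bool)  # 100x100 µm at 0.1 µm/px
        wins = place_density_windows(region, 0.1, window_um=20.0, seed=1)
        assert len(wins) == 3
        for i in range(3):
            assert wins[i].height == 200 and wins[i].width == 200
            for j in range(i + 1, 3):
                assert not wins[i].overlaps(wins[j])

    def test_same_seed_same_windows(self):
        region = np.ones((500, 500), bool)
        a = place_density_windows(region, 0.1, window_um=10.0, seed=7)
        b = place_density_windows(region, 0.1, window_um=10.0, seed=7)
        assert a == b

    def test_pigeonhole_failure_is_geometry_error(self):
        region = np.ones((1000, 1000), bool)
        with pytest.raises(GeometryError):
            place_density_windows(region, 0.1, window_um=60.0, seed=1)

    def test_windows_fit_inside_irregular_region(self):
        yy, xx = np.mgrid[:400, :400]
        region = (xx - 200) ** 2 + (yy - 200) ** 2 <= 180**2
        wins = place_density_windows(region, 0.1, window_um=8.0, seed=3)
        for w in wins:
            assert region[w.row0 : w.row0 + w.height, w.col0 : w.col0 + w.width].all()


class TestMeasureDensity:
    def _spotset(self, centers, ps=0.5):
        n = len(centers)
        return SpotSet(np.asarray(centers, float), np.full(n, 0.6), np.ones(n), ps)

    def _windows(self):
        # 50 µm² windows: at 0.5 µm/px a 20x10 px rect covers exactly 50 µm²
        return [Window(0, 0, 20, 10), Window(0, 15, 20, 10), Window(0, 30, 20, 10)]

    def test_25_spots_in_50um2_is_density_50(self):
        centers = [(r % 20 + 0.5, r // 20 + 0.5) for r in range(25)]
        dm = measure_density(self._spotset(centers), self._windows())
        assert dm.windows[0].count == 25
        assert dm.windows[0].density_per_100um2 == 50.0
        assert dm.oocyte_density == pytest.approx(50.0 / 3)

    def test_no_spots_gives_zero_density(self):
        dm = measure_density(self._spotset(np.empty((0, 2))), self._windows())
        assert dm.oocyte_density == 0.0

    def test_requires_exactly_three_windows(self):
        with pytest.raises(ValidationError, match="three"):
            measure_density(self._spotset(np.empty((0, 2))), self._windows()[:2])

    def test_overlapping_windows_rejected(self):
        wins = [Window(0, 0, 20, 10), Window(0, 5, 20, 10), Window(0, 30, 20, 10)]
        with pytest.raises(ValidationError, match="overlap"):
            measure_density(self._spotset(np.empty((0, 2))), wins)

    def test_shared_edge_spot_counted_once(self):
        """A centre exactly on the boundary between two adjacent windows
        belongs to exactly one (half-open convention)."""
        wins = [Window(0, 0, 20, 10), Window(0, 10, 20, 10), Window(0, 30, 20, 10)]
        dm = measure_density(self._spotset([(5.0, 10.0)]), wins)
        assert sum(w.count for w in dm.windows) == 1
        assert dm.windows[1].count == 1

    def test_count_additivity(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(0, 40, (300, 2))
        wins = self._windows()
        dm = measure_density(self._spotset(centers), wins)
        inside = sum(
            1 for r, c in centers if any(w.contains(r, c) for w in wins)
        )
        assert sum(w.count for w in dm.windows) == inside
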