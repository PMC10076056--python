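"""LNMS peak extraction against a brute-force oracle, plus point matching."""

import numpy as np
import pytest

import paddycount as pc
from paddycount.groundtruth import DensityGrid
from paddycount.localization import LNMSParams, window_size


def lnms_oracle(values: np.ndarray, w: int, threshold_fraction: float,
                min_peak: float, scale: int) -> np.ndarray:
    """O(n w^2) reference: explicit window maximality + both thresholds.

    Computed in float64 throughout, matching the precision the
    implementation uses for its threshold arithmetic.
    """
    values = np.asarray(values, np.float64)
    m = values.max() if values.size else 0.0
    if m < min_peak:
        return np.empty((0, 2))
    out = []
    rows, cols = values.shape
    half = w // 2
    for i in range(rows):
        for j in range(cols):
            window = values[max(i - half, 0):i + half + 1, max(j - half, 0):j + half + 1]
            if values[i, j] == window.max() and values[i, j] > m * threshold_fraction:
                out.append((j * scale, i * scale))
    return np.asarray(out, float).reshape(-1, 2)


class TestLnms:
    def test_all_zero_map_is_empty(self):
        pts = pc.lnms(DensityGrid(np.zeros((16, 16), np.float32)), d_mean=10.0)
        assert len(pts) == 0

    def test_below_min_peak_is_empty(self):
        vals = np.full((16, 16), 0.005, np.float32)
        assert len(pc.lnms(DensityGrid(vals), d_mean=10.0)) == 0

    def test_single_peak_hand_trace(self):
        vals = np.zeros((9, 9), np.float32)
        vals[4, 4] = 0.5
        pts = pc.lnms(DensityGrid(vals, scale=2), d_mean=10.0)  # window 3
        assert np.array_equal(pts.points, [[8.0, 8.0]])

    @pytest.mark.parametrize("w", [3, 5, 7])
    def test_matches_oracle_on_random_grids(self, w):
        rng = np.random.default_rng(w)
        params = LNMSParams()
        for trial in range(30):
            vals = np.abs(rng.normal(size=(32, 32))).astype(np.float32)
            if trial % 4 == 0:
                vals = np.round(vals, 1)  # quantize to force plateau ties
            if trial % 7 == 0:
                vals *= 1e-3  # exercise the empty branch
            got = pc.lnms(DensityGrid(vals, scale=2), d_mean=w / 0.3, params=params)
            exp = lnms_oracle(vals, w, params.threshold_fraction, params.min_peak, 2)
            assert np.array_equal(got.points, exp)

    def test_raising_threshold_never_adds_detections(self, rng):
        vals = np.abs(rng.normal(size=(24, 24))).astype(np.float32)
        counts = []
        for tf in (0.1, 0.3, 0.6, 0.9):
            pts = pc.lnms(DensityGrid(vals), 10.0,
                          LNMSParams(threshold_fraction=tf))
            counts.append(len(pts))
        assert counts == sorted(counts, reverse=True)

    def test_recovers_well_separated_ground_truth_centers(self):
        # plants on grid cells spaced 16 cells apart, sigma small
        centers_img = [[16.0, 16.0], [48.0, 16.0], [16.0, 48.0], [48.0, 48.0]]
        den = pc.make_density_map(pc.PointSet(centers_img), (32, 32), sigma=1.0)
        d_mean = pc.pseudo_mean_size(pc.PointSet(centers_img), k=2)
        got = pc.lnms(den, d_mean / den.scale)
        assert sorted(map(tuple, got.points)) == sorted(map(tuple, centers_img))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            pc.lnms(DensityGrid(np.ones((4, 4), np.float32)), d_mean=0.0)
        with pytest.raises(ValueError):
            LNMSParams(kernel_fraction=0.0)

    @pytest.mark.parametrize("d_mean,expected", [(5.0, 3), (10.0, 3), (17.0, 5), (23.4, 7)])
    def test_window_rounding_to_odd(self, d_mean, expected):
        assert window_size(d_mean) == expected


class TestMatchPoints:
    def test_identical_sets_all_hit(self, rng):
        pts = pc.PointSet(rng.uniform(0, 100, (12, 2)))
        assert pc.match_points(pts, pts, radius=1.0) == (12, 0, 0)

    def test_empty_prediction_all_missed(self, rng):
        truth = pc.PointSet(rng.uniform(0, 100, (7, 2)))
        assert pc.match_points(pc.PointSet(), truth, radius=5.0) == (0, 7, 0)

    def test_small_perturbation_all_hit(self, rng):
        truth = rng.uniform(20, 200, (20, 2))
        radius = 8.0
        noise = rng.uniform(-radius / (2 * np.sqrt(2)), radius / (2 * np.sqrt(2)), (20, 2))
        pred = pc.PointSet(truth + noise)
        hits, misses, fas = pc.match_points(pred, pc.PointSet(truth), radius)
        assert (hits, misses, fas) == (20, 0, 0)

    def test_extra_predictions_are_false_alarms(self, rng):
        truth = rng.uniform(0, 100, (5, 2))
        pred = np.vstack([truth, [[500.0, 500.0]]])
        assert pc.match_points(pc.PointSet(pred), pc.PointSet(truth), 1.0) == (5, 0, 1)

    def test_matching_is_one_to_one(self):
        truth = pc.PointSet([[0.0, 0.0]])
        pred = pc.PointSet([[1.0, 0.0], [2.0, 0.0]])
        hits, misses, fas = pc.match_points(pred, truth, radius=5.0)
        assert (hits, misses, fas) == (1, 0, 1)
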