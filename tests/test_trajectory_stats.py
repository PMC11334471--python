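"""Ordination, trajectories, stability classification, correlation and
broken-stick regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from backslop import trajectory_stats as ts
from backslop.community_metrics import DynamicsSummary
from backslop.io_formats import PipelineConfig


class TestNMDS:
    def test_three_equidistant_points_embed_perfectly(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        res = ts.nmds(d, k=2, seed=0, n_restarts=8)
        assert res.stress < 0.02
        dists = pdist(res.coords.to_numpy())
        assert np.ptp(dists) / dists.mean() < 0.05  # near-equilateral

    def test_zero_matrix_collapses_with_zero_stress(self):
        res = ts.nmds(np.zeros((5, 5)), k=2, seed=0, n_restarts=4)
        assert res.stress == 0.0
        assert np.all(res.coords.to_numpy() == 0.0)

    def test_recovers_embeddable_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.random((30, 2))
        d = squareform(pdist(pts))
        d = d / d.max()  # BC-like scale in [0, 1]
        res = ts.nmds(d, k=2, seed=0, n_restarts=16)
        out = squareform(pdist(res.coords.to_numpy()))
        iu = np.triu_indices(30, 1)
        rho = stats.spearmanr(d[iu], out[iu]).statistic
        assert rho > 0.9

    def test_deterministic_and_stress_monotone_in_restarts(self):
        rng = np.random.default_rng(4)
        pts = rng.random((15, 2))
        d = squareform(pdist(pts))
        a = ts.nmds(d, seed=7, n_restarts=4)
        b = ts.nmds(d, seed=7, n_restarts=4)
        assert np.array_equal(a.coords.to_numpy(), b.coords.to_numpy())
        c = ts.nmds(d, seed=7, n_restarts=8)
        assert c.stress <= a.stress + 1e-15

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 0.2], [0.3, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ts.nmds(d)

    def test_coordinates_centered(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.random((10, 2))))
        res = ts.nmds(d, seed=1, n_restarts=4)
        assert np.allclose(res.coords.mean(axis=0), 0.0, atol=1e-12)


def coords_df(points, labels=None):
    labels = labels or [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(points, index=labels, columns=["axis1", "axis2"])


class TestTrajectories:
    def test_coincident_points_zero_lengths(self):
        df = coords_df([[0.3, -0.1]] * 5)
        t = ts.lineage_trajectory(df, list(df.index), "M1")
        assert t.total_length == 0.0 and t.net_displacement == 0.0

    def test_collinear_path_attains_equality(self):
        df = coords_df([[i, 0.0] for i in range(5)])
        t = ts.lineage_trajectory(df, list(df.index))
        assert t.total_length == pytest.approx(t.net_displacement)
        assert t.direction_angle == pytest.approx(0.0)

    def test_closed_path_net_much_smaller_than_total(self):
        df = coords_df([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0.01]])
        t = ts.lineage_trajectory(df, list(df.index))
        assert t.total_length == pytest.approx(3.99, abs=1e-9)
        assert t.net_displacement == pytest.approx(0.01, abs=1e-12)
        assert t.total_length >= t.net_displacement

    def test_missing_sample_is_error(self):
        df = coords_df([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="missing"):
            ts.lineage_trajectory(df, ["s0", "ghost"])


class TestParallelism:
    @staticmethod
    def _traj(angle):
        return ts.TrajectoryStats("x", [1.0], 1.0, 1.0, angle)

    def test_identical_directions(self):
        assert ts.trajectory_parallelism([self._traj(0.3)] * 3) == pytest.approx(1.0)

    def test_orthogonal_directions(self):
        got = ts.trajectory_parallelism([self._traj(0.0), self._traj(math.pi / 2)])
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_directions(self):
        got = ts.trajectory_parallelism([self._traj(0.0), self._traj(math.pi)])
        assert got == pytest.approx(-1.0)

    def test_zero_displacement_excluded(self):
        trajs = [self._traj(0.0), self._traj(0.0),
                 ts.TrajectoryStats("z", [0.0], 0.0, 0.0, 0.0)]
        assert ts.trajectory_parallelism(trajs) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ts.trajectory_parallelism([trajs[2], trajs[2]])


class TestPearsonTrend:
    def test_perfectly_increasing(self):
        r, p, flags = ts.pearson_trend([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        assert flags == ()

    def test_constant_series_flagged(self):
        r, p, flags = ts.pearson_trend([2, 2, 2], [1, 2, 3])
        assert np.isnan(r) and "undefined_zero_variance" in flags

    def test_known_example(self):
        r, p, _ = ts.pearson_trend([2, 1, 4, 3, 5], [1, 2, 3, 4, 5])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r, _, _ = ts.pearson_trend(y, x)
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            assert r == pytest.approx(expected, abs=1e-12)


class TestStructureFunctionCorrelation:
    def test_scaled_identity_gives_r_one(self):
        rng = np.random.default_rng(1)
        dph = rng.uniform(-0.3, 0.3, 50)
        bc = 2.5 * np.abs(dph)
        r, p, n = ts.correlate_structure_function(bc, dph, use_abs=True)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 50

    def test_independent_noise_is_uncorrelated(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            bc = rng.random(1000)
            dph = rng.normal(size=1000)
            r, _, _ = ts.correlate_structure_function(bc, dph)
            hits += abs(r) < 0.1
        assert hits >= 38  # >= 95 %

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError):
            ts.correlate_structure_function([0.1, 0.2], [0.1, 0.2])

    def test_nan_pairs_dropped(self):
        bc = [0.1, 0.2, 0.3, np.nan, 0.5]
        dph = [0.01, 0.02, 0.03, 0.04, np.nan]
        r, p, n = ts.correlate_structure_function(bc, dph)
        assert n == 3


def summary_with(bc, doms):
    s = DynamicsSummary(lineage_id="M1")
    steps = ["F2", "F3", "F4", "F5", "F6"]
    s.bc_adjacent = [(f"{a}-{b}", v) for (a, b), v in
                     zip(zip(steps, steps[1:]), bc)]
    s.dominant_taxon_series = dict(zip(steps, doms))
    return s


class TestClassifyStability:
    def test_low_constant_bc_is_stable(self):
        s = summary_with([0.03] * 4, ["Lactococcus"] * 5)
        assert ts.classify_stability(s).label == "stable"

    def test_decreasing_bc_with_dominance_switch_is_successional(self):
        s = summary_with([0.31, 0.25, 0.18, 0.14],
                         ["Lactococcus", "Lactococcus", "none",
                          "Lactobacillus sensu lato", "Lactobacillus sensu lato"])
        lab = ts.classify_stability(s)
        assert lab.label == "successional"
        assert lab.evidence["dominance_switch"] is True

    def test_intermediate_bc_same_dominant_is_drifting(self):
        s = summary_with([0.13] * 4, ["Lactococcus"] * 5)
        lab = ts.classify_stability(s)
        assert lab.label == "drifting"
        assert lab.evidence["mean_bc"] == pytest.approx(0.13)

    def test_high_decreasing_bc_without_switch_is_successional(self):
        s = summary_with([0.35, 0.28, 0.2, 0.12], ["none"] * 5)
        assert ts.classify_stability(s).label == "successional"

    def test_insufficient_pairs_unclassified(self):
        s = summary_with([0.1, 0.1], ["Lactococcus"] * 3)
        assert ts.classify_stability(s).label == "unclassified"

    def test_custom_thresholds_respected(self):
        s = summary_with([0.1] * 4, ["Lactococcus"] * 5)
        cfg = PipelineConfig(stability_bc_low=0.15)
        assert ts.classify_stability(s, cfg).label == "stable"


class TestBreakpointRegression:
    @staticmethod
    def planted(rng, n=150, bp=88.0, s_left=0.0, s_right=0.09, noise=0.0,
                lo=50.0, hi=100.0):
        x = rng.uniform(lo, hi, n)
        y = 2.0 + s_left * x + (s_right - s_left) * np.maximum(x - bp, 0.0)
        if noise:
            y = y + rng.normal(0, noise, n)
        return x, y

    def test_noiseless_planted_model_recovered_exactly(self):
        x, y = self.planted(np.random.default_rng(0))
        fit = ts.breakpoint_regression(x, y, grid_step=0.5)
        assert fit.breakpoint == pytest.approx(88.0, abs=0.5)
        assert fit.slope_left == pytest.approx(0.0, abs=1e-6)
        assert fit.slope_right == pytest.approx(0.09, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_pure_line_flags_no_breakpoint_support(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 80)
        y = 1.0 + 0.5 * x
        fit = ts.breakpoint_regression(x, y)
        assert "no_breakpoint_support" in fit.flags
        assert fit.rss <= fit.rss_single_line * (1 + 1e-9)

    def test_rss_never_exceeds_single_line(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(0, 1, 40)
            y = rng.normal(size=40)
            fit = ts.breakpoint_regression(x, y)
            assert fit.rss <= fit.rss_single_line * (1 + 1e-9) + 1e-12

    def test_degenerate_x_falls_back_to_single_line(self):
        x = np.full(20, 0.5) + np.linspace(0, 1e-4, 20)
        y = np.arange(20.0)
        fit = ts.breakpoint_regression(x, y, grid_step=0.005)
        assert "single_line_fallback" in fit.flags
        assert np.isnan(fit.breakpoint)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ts.breakpoint_regression(np.arange(5.0), np.arange(5.0))
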