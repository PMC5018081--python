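import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capmotion as cm
from capmotion.errors import ValidationError


def _track(positions):
    return np.asarray(positions, dtype=float)


class TestMsd:
    def test_static_track_is_zero(self):
        p = np.zeros((10, 3))
        for tau in (1, 3, 9):
            assert cm.msd(p, tau) == 0.0

    @pytest.mark.parametrize("v,tau", [(1.0, 1), (0.5, 3), (2.0, 5)])
    def test_ballistic_closed_form(self, v, tau):
        t = np.arange(12.0)
        p = np.column_stack([v * t, np.zeros_like(t), np.zeros_like(t)])
        assert cm.msd(p, tau) == pytest.approx((v * tau) ** 2)

    def test_short_track_excluded_not_zero(self):
        assert cm.msd(np.zeros((3, 3)), 5) is None

    def test_brownian_pooled_slope(self, rng):
        sigma = 1.5
        vals = []
        for _ in range(500):
            steps = rng.normal(scale=sigma, size=(20, 3))
            p = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            for tau in (1, 2, 4):
                vals.append((tau, cm.msd(p, tau)))
        df = pd.DataFrame(vals, columns=["tau", "msd"]).groupby("tau").mean()
        for tau in (1, 2, 4):
            assert df.loc[tau, "msd"] == pytest.approx(3 * sigma**2 * tau, rel=0.05)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), angle=st.floats(0, 2 * np.pi))
    def test_invariant_under_rigid_motion(self, seed, angle):
        r = np.random.default_rng(seed)
        p = np.cumsum(r.normal(size=(12, 3)), axis=0)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        q = p @ rot.T + r.uniform(-100, 100, 3)
        for tau in (1, 4):
            assert cm.msd(q, tau) == pytest.approx(cm.msd(p, tau), rel=1e-9)
            assert cm.velocity_autocorrelation(q, tau) == pytest.approx(
                cm.velocity_autocorrelation(p, tau), rel=1e-7, abs=1e-9
            )


class TestAutocorrelation:
    def test_constant_velocity_is_one_at_every_lag(self):
        t = np.arange(15.0)
        p = np.column_stack([2 * t, -t, 0.3 * t])
        for tau in (1, 5, 10):
            assert cm.velocity_autocorrelation(p, tau) == pytest.approx(1.0)

    def test_alternating_steps(self):
        x = np.array([0.0, 1, 0, 1, 0, 1, 0, 1, 0])
        p = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        assert cm.velocity_autocorrelation(p, 1) == pytest.approx(-1.0)
        assert cm.velocity_autocorrelation(p, 2) == pytest.approx(1.0)

    def test_iid_steps_average_to_zero(self, rng):
        vals = []
        for _ in range(500):
            p = np.cumsum(rng.normal(size=(22, 3)), axis=0)
            vals.append(cm.velocity_autocorrelation(p, 1))
        assert abs(np.mean(vals)) < 0.02

    def test_only_horizontal_components_used(self, rng):
        p = np.cumsum(rng.normal(size=(15, 3)), axis=0)
        q = p.copy()
        q[:, 2] = rng.normal(scale=30, size=15)  # arbitrary z perturbation
        for tau in (1, 2):
            assert cm.velocity_autocorrelation(q, tau) == pytest.approx(
                cm.velocity_autocorrelation(p, tau)
            )

    def test_zero_movement_track_excluded(self):
        assert cm.velocity_autocorrelation(np.zeros((10, 3)), 1) is None

    def test_bounded_by_one_for_stationary_tracks(self, rng):
        for _ in range(50):
            p = np.cumsum(rng.normal(size=(30, 3)), axis=0)
            v = cm.velocity_autocorrelation(p, 1)
            assert v <= 1.0 + 1e-12


class TestAggregation:
    def test_single_track_curve_equals_per_track_msd(self):
        t = np.arange(10.0)
        cells = pd.DataFrame(
            {"sample": "s", "crop": "c", "track": "t", "branch": "0", "time": t.astype(int),
             "pos_x": 2 * t, "pos_y": 0.0, "pos_z": 0.0}
        )
        curve = cm.aggregate_msd(cells, {"s": 20}, taus=[1, 2, 3])
        for _, row in curve.iterrows():
            assert row["msd"] == pytest.approx((2 * row["tau"]) ** 2)
            assert row["n_tracks"] == 1

    def test_duplicate_tracks_do_not_change_mean(self):
        t = np.arange(8.0)
        one = pd.DataFrame(
            {"sample": "s", "crop": "c", "track": "t1", "branch": "0", "time": t.astype(int),
             "pos_x": t, "pos_y": t, "pos_z": 0.0}
        )
        two = pd.concat([one, one.assign(track="t2")], ignore_index=True)
        c1 = cm.aggregate_msd(one, {"s": 20}, taus=[1, 2])
        c2 = cm.aggregate_msd(two, {"s": 20}, taus=[1, 2])
        np.testing.assert_allclose(c1["msd"], c2["msd"])

    def test_groups_split_by_step_minutes(self):
        t = np.arange(6.0)
        a = pd.DataFrame(
            {"sample": "sA", "crop": "c", "track": "t1", "branch": "0", "time": t.astype(int),
             "pos_x": t, "pos_y": 0.0, "pos_z": 0.0}
        )
        b = a.assign(sample="sB")
        curve = cm.aggregate_msd(pd.concat([a, b]), {"sA": 15, "sB": 20}, taus=[1])
        assert sorted(curve["step_minutes"]) == [15, 20]

    def test_unknown_step_minutes_raises(self):
        t = np.arange(4.0)
        a = pd.DataFrame(
            {"sample": "sA", "crop": "c", "track": "t1", "branch": "0", "time": t.astype(int),
             "pos_x": t, "pos_y": 0.0, "pos_z": 0.0}
        )
        with pytest.raises(ValidationError):
            cm.aggregate_msd(a, {}, taus=[1])


class TestSpeedHeterogeneity:
    def test_identical_speeds_give_zero_reduction(self):
        speeds = pd.DataFrame(
            {"sample": "s", "crop": "c", "track": [f"t{i}" for i in range(4) for _ in range(5)],
             "branch": "0", "time": list(range(5)) * 4, "speed": 1.0}
        )
        het = cm.speed_heterogeneity(speeds)
        assert het.rss_reduction_percent == pytest.approx(0.0, abs=1e-9)

    def test_planned_variance_fraction_recovered(self, rng):
        """Between-cell variance engineered to explain ~20% of within-sample variance."""
        f = 0.20
        sd_cell, sd_noise = np.sqrt(f), np.sqrt(1 - f)
        rows = []
        for sample, offset in (("sA", 3.0), ("sB", 5.0)):
            for c in range(40):
                mu = offset + rng.normal(scale=sd_cell)
                for t in range(60):
                    rows.append((sample, "c", f"t{c}", "0", t, mu + rng.normal(scale=sd_noise)))
        speeds = pd.DataFrame(rows, columns=["sample", "crop", "track", "branch", "time", "speed"])
        het = cm.speed_heterogeneity(speeds)
        # independent ANOVA decomposition: within-sample SS vs within-cell SS
        y = speeds["speed"]
        rss_sample = sum(
            ((g - g.mean()) ** 2).sum() for _, g in y.groupby(speeds["sample"])
        )
        rss_cell = sum(
            ((g - g.mean()) ** 2).sum()
            for _, g in y.groupby([speeds["sample"], speeds["track"]])
        )
        expected = 100 * (rss_sample - rss_cell) / rss_sample
        assert het.rss_reduction_percent == pytest.approx(expected, abs=1e-8)
        assert het.rss_reduction_percent == pytest.approx(100 * f, abs=6.0)
        assert het.p_value < 1e-10

    def test_strong_heterogeneity_on_simulation_detected(self, rng):
        rows = []
        for c in range(15):
            mu = rng.uniform(0.5, 4.0)
            for t in range(30):
                rows.append(("s", "c", f"t{c}", "0", t, abs(mu + rng.normal(scale=0.3))))
        speeds = pd.DataFrame(rows, columns=["sample", "crop", "track", "branch", "time", "speed"])
        het = cm.speed_heterogeneity(speeds)
        assert het.f_statistic > 10
        assert het.p_value < 1e-6


class TestEdgeExclusion:
    BOUNDS = {("s", "c"): (0.0, 100.0, 0.0, 50.0, 0.0, 30.0)}

    def _spots(self, xy):
        return pd.DataFrame(
            {"sample": "s", "crop": "c", "track": "t", "branch": "0",
             "time": range(len(xy)),
             "pos_x": [p[0] for p in xy], "pos_y": [p[1] for p in xy], "pos_z": 15.0}
        )

    def test_center_kept_near_edge_dropped_boundary_kept(self):
        spots = self._spots([(50, 25), (0.5, 25), (1.0, 25), (50, 49.5), (99.0, 1.0)])
        keep = cm.exclude_near_edge(spots, self.BOUNDS)
        assert keep.tolist() == [True, False, True, False, True]

    def test_exclusion_is_lateral_only(self):
        spots = self._spots([(50, 25)])
        spots["pos_z"] = 0.01  # touching the z boundary is irrelevant
        assert cm.exclude_near_edge(spots, self.BOUNDS).all()

    def test_missing_bounds_instructs_user(self):
        spots = self._spots([(50, 25)])
        with pytest.raises(ValidationError, match="bounds"):
            cm.exclude_near_edge(spots, {})


def _context_and_corrected(tip_vec, moves, d=None):
    """Minimal one-segment context/corrected tables for projection tests."""
    n = len(moves) + 1
    pos = np.vstack([np.zeros(3), np.cumsum(moves, axis=0)])
    tip_vec = np.asarray(tip_vec, float)
    ctx = pd.DataFrame(
        {"sample": "s", "crop": "c", "track": "t", "branch": "0", "time": range(n),
         "pos_x": pos[:, 0], "pos_y": pos[:, 1], "pos_z": pos[:, 2],
         "tip_dx": tip_vec[0], "tip_dy": tip_vec[1], "tip_dz": tip_vec[2],
         "tip_distance": d if d is not None else np.linalg.norm(tip_vec)}
    )
    return ctx, ctx[["sample", "crop", "track", "branch", "time", "pos_x", "pos_y", "pos_z"]]


class TestTipDirectedMovement:
    def test_movement_parallel_to_tip_direction(self):
        ctx, corr = _context_and_corrected((0, 0, 5), [(0, 0, 2.0)])
        moves = cm.tip_directed_movement(ctx, corr)
        assert moves["m"].iloc[0] == pytest.approx(2.0)

    def test_orthogonal_movement_scores_zero(self):
        ctx, corr = _context_and_corrected((0, 0, 5), [(3.0, 0, 0)])
        moves = cm.tip_directed_movement(ctx, corr)
        assert moves["m"].iloc[0] == pytest.approx(0.0)

    def test_dot_product_arithmetic(self):
        ctx, corr = _context_and_corrected((0, 3.0, 4.0), [(1.0, 2.0, 2.0)])
        moves = cm.tip_directed_movement(ctx, corr)
        # unit vector (0, 0.6, 0.8) . (1, 2, 2) = 2.8
        assert moves["m"].iloc[0] == pytest.approx(2.8)

    def test_projection_never_exceeds_movement_magnitude(self, default_pipeline):
        moves = cm.tip_directed_movement(
            default_pipeline["context"], default_pipeline["corrected"]
        )
        assert (moves["m"].abs() <= moves["move_3d"] + 1e-9).all()
        # group-level: mean |movement| >= |mean projection|
        for _, grp in moves.groupby(moves["d"] < 10):
            assert grp["move_3d"].mean() >= abs(grp["m"].mean())


class TestAttractionRepulsion:
    @staticmethod
    def _moves(rng, n, d_lo, d_hi, bias):
        return pd.DataFrame(
            {"d": rng.uniform(d_lo, d_hi, n), "m": bias + rng.normal(scale=1.0, size=n),
             "move_xy": np.abs(rng.normal(scale=2, size=n)),
             "move_3d": np.abs(rng.normal(scale=2, size=n)) + 2}
        )

    def test_known_bias_recovered(self, rng):
        far = self._moves(rng, 4000, 10.5, 30, bias=0.2)
        near = self._moves(rng, 2000, 0, 9.5, bias=-0.3)
        out = cm.attraction_repulsion_tests(pd.concat([far, near], ignore_index=True))
        near_row = out[out["group"] == "d<10"].iloc[0]
        far_row = out[out["group"] == "d>10"].iloc[0]
        assert far_row["mean_m"] == pytest.approx(0.2, abs=0.06)
        assert near_row["mean_m"] == pytest.approx(-0.3, abs=0.08)
        assert far_row["p"] < 1e-6 and near_row["p"] < 1e-6

    def test_tiny_group_reports_counts_without_test(self, rng):
        moves = self._moves(rng, 1, 0, 5, bias=0.0)
        out = cm.attraction_repulsion_tests(moves)
        near_row = out[out["group"] == "d<10"].iloc[0]
        assert near_row["n"] == 1 and np.isnan(near_row["p"])


class TestDistanceTrendRegression:
    def test_null_slope_near_zero(self, rng):
        moves = pd.DataFrame({"d": rng.uniform(15.5, 40, 5000),
                              "m": rng.normal(scale=1, size=5000)})
        slope, p = cm.distance_trend_regression(moves)
        assert abs(slope) < 0.02

    def test_ols_recovers_planted_slope(self, rng):
        d = rng.uniform(15.5, 45, 4000)
        moves = pd.DataFrame({"d": d, "m": 0.01 * d + rng.normal(scale=0.2, size=4000)})
        slope, p = cm.distance_trend_regression(moves)
        assert slope == pytest.approx(0.01, abs=0.002)
        assert p < 1e-6

    def test_degenerate_distances_raise(self):
        moves = pd.DataFrame({"d": [20.0] * 10, "m": np.arange(10.0)})
        with pytest.raises(ValidationError):
            cm.distance_trend_regression(moves)
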