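"""Water-maze strategy classification and behavioral normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from atlasvol.behavior_metrics import (
    CHANCE_LEVEL_PCT,
    PoolGeometry,
    StrategyCall,
    SUBSTRATEGY_CLASS,
    Trajectory,
    classify_strategy,
    epm_ratios,
    percent_of_control,
    strategy_percentages,
)
from atlasvol.synthetic import SUBSTRATEGIES, make_trajectories


class TestTrajectoryType:
    def test_pool_escape_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            Trajectory([0, 1], [0, 90.0], [0, 0])

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory([0, 1, 1], [0, 1, 2], [0, 0, 0])

    def test_too_short_rejected(self):
        tr = Trajectory([0.0, 0.5], [0, 1], [0, 1])
        with pytest.raises(ValueError, match="1 s"):
            classify_strategy(tr)


class TestConstructedCases:
    def test_straight_line_to_platform_is_spatial_direct(self):
        pool = PoolGeometry()
        start = np.array([-50.0, -50.0])
        plat = np.asarray(pool.platform_center)
        n = 40
        pts = start + np.linspace(0, 1, n)[:, None] * (plat - start)
        tr = Trajectory(np.arange(n) / 10.0, pts[:, 0], pts[:, 1], pool=pool)
        call = classify_strategy(tr)
        assert call.substrategy == "spatial_direct"
        assert call.strategy_class == "spatial"
        assert call.diagnostics["efficiency"] > 0.9

    def test_wall_annulus_is_peripheral_looping(self):
        pool = PoolGeometry()
        ang = np.linspace(0, 3 * np.pi, 400)
        r = 0.92 * pool.radius_cm  # within 10 cm of the wall throughout
        tr = Trajectory(np.arange(400) / 10.0, r * np.cos(ang),
                        r * np.sin(ang), pool=pool)
        call = classify_strategy(tr)
        assert call.substrategy == "peripheral_looping"
        assert call.strategy_class == "repetitive_looping"


class TestGeneratorRoundTrip:
    @pytest.fixture(scope="class")
    def batch(self):
        calls = []
        for sub in SUBSTRATEGIES:
            for tr in make_trajectories(sub, 10, seed=20160504):
                calls.append((sub, classify_strategy(tr)))
        return calls

    def test_substrategy_accuracy_at_least_80pct(self, batch):
        acc = np.mean([true == call.substrategy for true, call in batch])
        assert acc >= 0.80

    def test_class_accuracy_at_least_90pct(self, batch):
        acc = np.mean([SUBSTRATEGY_CLASS[true] == call.strategy_class
                       for true, call in batch])
        assert acc >= 0.90

    def test_rotation_invariance(self):
        # rotating pool, platform, and path together must not change calls
        theta = math.radians(40.0)
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        for sub in ("spatial_direct", "chaining", "peripheral_looping"):
            tr = make_trajectories(sub, 1, seed=3)[0]
            call0 = classify_strategy(tr)
            xy = np.stack([tr.x_cm, tr.y_cm], 1) @ R.T
            plat = R @ np.asarray(tr.pool.platform_center)
            pool = PoolGeometry(platform_center=tuple(plat))
            tr_rot = Trajectory(tr.t_s, xy[:, 0], xy[:, 1], pool=pool)
            assert classify_strategy(tr_rot).substrategy == call0.substrategy


class TestStrategyPercentages:
    def _call(self, sub, subject="s", day=1, trial=0):
        return StrategyCall(sub, SUBSTRATEGY_CLASS[sub], subject=subject,
                            day=day, trial=trial)

    def test_all_spatial_gives_100(self):
        calls = [self._call("spatial_direct", trial=i) for i in range(4)]
        pct, _ = strategy_percentages(calls)
        cls = pct[pct["level"] == "class"].set_index("name")["percent"]
        assert cls["spatial"] == 100.0
        assert cls["non_spatial_systematic"] == 0.0

    def test_uniform_use_hits_chance_level(self):
        calls = [self._call(s, trial=i) for i, s in enumerate(SUBSTRATEGIES)]
        pct, _ = strategy_percentages(calls)
        subs = pct[pct["level"] == "substrategy"]
        assert np.allclose(subs["percent"], CHANCE_LEVEL_PCT)
        assert np.isclose(CHANCE_LEVEL_PCT, 11.1111, atol=1e-3)

    def test_2_1_1_class_split(self):
        calls = [self._call("spatial_direct", trial=0),
                 self._call("focal_correct", trial=1),
                 self._call("random", trial=2),
                 self._call("chaining", trial=3)]
        pct, _ = strategy_percentages(calls)
        cls = pct[pct["level"] == "class"].set_index("name")["percent"]
        assert cls["spatial"] == 50.0
        assert cls["non_spatial_systematic"] == 25.0
        assert cls["repetitive_looping"] == 25.0

    def test_class_percentages_sum_to_100_per_day(self):
        rng = np.random.default_rng(0)
        calls = [self._call(rng.choice(SUBSTRATEGIES), subject=f"m{i%4}",
                            day=1 + i % 3, trial=i) for i in range(60)]
        pct, _ = strategy_percentages(calls)
        sums = (pct[pct["level"] == "class"]
                .groupby("day")["percent"].sum())
        assert np.allclose(sums, 100.0)


class TestPercentOfControl:
    def test_control_group_mean_is_100(self):
        df = pd.DataFrame({"dose_gy": [0.0, 0.0, 1.0],
                           "act": [90.0, 110.0, 60.0]})
        out = percent_of_control(df, "act")
        assert np.isclose(out[df["dose_gy"] == 0.0].mean(), 100.0)

    def test_simple_ratio(self):
        df = pd.DataFrame({"dose_gy": [0.0, 1.0], "v": [100.0, 90.0]})
        assert np.isclose(percent_of_control(df, "v").iloc[1], 90.0)

    def test_generated_dose_effect_recovered(self):
        rng = np.random.default_rng(11)
        ctrl = rng.normal(100, 8, 18)
        top = rng.normal(70, 8, 10)
        df = pd.DataFrame({"dose_gy": [0.0] * 18 + [1.0] * 10,
                           "act": np.concatenate([ctrl, top])})
        out = percent_of_control(df, "act")
        top_mean = out[df["dose_gy"] == 1.0].mean()
        # delta-method SEM of the ratio-of-means includes the sampling
        # uncertainty of the control mean itself
        sem = 70.0 * math.sqrt(8**2 / (10 * 70.0**2) + 8**2 / (18 * 100.0**2))
        assert abs(top_mean - 70.0) < 3 * sem

    def test_empty_control_rejected(self):
        df = pd.DataFrame({"dose_gy": [1.0], "v": [1.0]})
        with pytest.raises(ValueError, match="control"):
            percent_of_control(df, "v")


class TestEPM:
    @pytest.mark.parametrize("op, cl, pct, ratio, defined", [
        (5, 5, 50.0, 1.0, True),
        (0, 10, 0.0, 0.0, True),
        (10, 0, 100.0, float("nan"), False),
    ])
    def test_ratios(self, op, cl, pct, ratio, defined):
        p, r, ok = epm_ratios(op, cl)
        assert p == pct and ok == defined
        if defined:
            assert r == ratio
        else:
            assert math.isnan(r)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            epm_ratios(-1, 5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            epm_ratios(0, 0)
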