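"""Kaplan-Meier, log-rank, BH adjustment and expression-group splits."""

import numpy as np
import pandas as pd
import pytest

from ishquant import survival as surv


def _records(times, events, groups=None, ids=None):
    n = len(times)
    return pd.DataFrame(
        {
            "patient_id": ids if ids is not None else [f"P{i}" for i in range(n)],
            "time": times,
            "event": events,
            "group": groups if groups is not None else ["all"] * n,
        }
    )


def hand_logrank_two_groups(records):
    """Independent oracle: textbook hypergeometric-moment log-rank statistic."""
    groups = sorted(records["group"].unique())
    assert len(groups) == 2
    times = np.sort(records.loc[records["event"] == 1, "time"].unique())
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        at_risk = records["time"] >= t
        n = at_risk.sum()
        n1 = (at_risk & (records["group"] == groups[0])).sum()
        d = ((records["time"] == t) & (records["event"] == 1)).sum()
        d1 = (
            (records["time"] == t)
            & (records["event"] == 1)
            & (records["group"] == groups[0])
        ).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        r = _records([3, 5, 8], [0, 0, 0])
        curves = surv.km_estimate(r)
        assert np.allclose(curves["all"]["survival"], 1.0)

    def test_two_event_product_limit_hand_computation(self):
        r = _records([1, 2], [1, 1])
        c = surv.km_estimate(r)["all"].set_index("time")["survival"]
        assert c.loc[0.0] == pytest.approx(1.0)
        assert c.loc[1.0] == pytest.approx(0.5)
        assert c.loc[2.0] == pytest.approx(0.0)

    def test_duplicating_records_leaves_curve_unchanged(self):
        r = _records([2, 4, 6, 9], [1, 0, 1, 1])
        doubled = pd.concat([r, r], ignore_index=True)
        c1 = surv.km_estimate(r)["all"]
        c2 = surv.km_estimate(doubled)["all"]
        pd.testing.assert_frame_equal(c1, c2)

    def test_curve_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(0)
        r = _records(rng.exponential(10, 40), rng.integers(0, 2, 40))
        c = surv.km_estimate(r)["all"]
        assert c["survival"].iloc[0] == pytest.approx(1.0)
        assert (np.diff(c["survival"]) <= 1e-12).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            surv.km_estimate(_records([-1, 2], [1, 1]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 3, 5, 8, 13]
        r = pd.concat(
            [
                _records(times, [1] * 5, ["a"] * 5),
                _records(times, [1] * 5, ["b"] * 5, ids=[f"Q{i}" for i in range(5)]),
            ],
            ignore_index=True,
        )
        stat, p = surv.logrank(r)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_data_matches_hand_computed_formula(self):
        r = _records(
            [1, 2, 3, 10, 11, 12], [1] * 6, ["a"] * 3 + ["b"] * 3
        )
        stat, _ = surv.logrank(r)
        assert stat == pytest.approx(hand_logrank_two_groups(r), rel=1e-9)

    def test_relabeling_groups_keeps_statistic(self):
        rng = np.random.default_rng(1)
        r = _records(
            rng.exponential(10, 30), rng.integers(0, 2, 30) | 1,
            rng.choice(["a", "b"], 30),
        )
        stat1, _ = surv.logrank(r)
        r2 = r.assign(group=r["group"].map({"a": "x", "b": "y"}))
        stat2, _ = surv.logrank(r2)
        assert stat1 == pytest.approx(stat2, rel=1e-12)

    def test_no_events_raise(self):
        r = _records([1, 2, 3, 4], [0] * 4, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="undefined|events"):
            surv.logrank(r)

    def test_matches_permutation_null_on_small_sample(self):
        """Chi-square reference p agrees with a permutation null within
        Monte-Carlo error (n = 12)."""
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 12)
        events = np.ones(12, int)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        r = _records(times, events, groups)
        stat_obs, p_chi = surv.logrank(r)
        perm_stats = []
        for _ in range(2000):
            g = rng.permutation(groups)
            perm_stats.append(hand_logrank_two_groups(r.assign(group=g)))
        p_perm = np.mean(np.asarray(perm_stats) >= stat_obs - 1e-12)
        assert abs(p_perm - p_chi) < 3 * np.sqrt(p_perm * (1 - p_perm) / 2000) + 0.03


class TestBH:
    def test_worked_step_up_example(self):
        adj = surv.bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert surv.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = surv.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestMedianSplit:
    def test_even_n_half_half(self):
        vals = pd.Series(np.arange(1.0, 11), index=[f"P{i}" for i in range(10)])
        rng = np.random.default_rng(4)
        rec = _records(rng.exponential(10, 10), [1] * 10, ids=vals.index)
        res = surv.median_split(vals, rec)
        assert sorted(res.groups.value_counts().tolist()) == [5, 5]

    def test_odd_n_median_goes_low(self):
        vals = pd.Series(np.arange(1.0, 10), index=[f"P{i}" for i in range(9)])
        rng = np.random.default_rng(5)
        rec = _records(rng.exponential(10, 9), [1] * 9, ids=vals.index)
        res = surv.median_split(vals, rec)
        counts = res.groups.value_counts()
        assert counts["low"] == 5 and counts["high"] == 4

    def test_all_equal_values_raise(self):
        vals = pd.Series([1.0] * 6, index=[f"P{i}" for i in range(6)])
        rec = _records([1, 2, 3, 4, 5, 6], [1] * 6, ids=vals.index)
        with pytest.raises(ValueError):
            surv.median_split(vals, rec)

    def test_null_simulation_type_one_error(self):
        """Median split on an uninformative covariate rejects at ~5%:
        empirical type-I error within [0.03, 0.07] over 1000 replicates."""
        rng = np.random.default_rng(6)
        n = 60
        rejections = 0
        reps = 1000
        ids = [f"P{i}" for i in range(n)]
        for _ in range(reps):
            vals = pd.Series(rng.random(n), index=ids)
            rec = _records(rng.exponential(20, n), [1] * n, ids=ids)
            res = surv.median_split(vals, rec)
            rejections += res.nominal_p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestThreeWaySplit:
    def test_candidate_grid_has_at_most_20_pairs(self):
        pairs = surv.candidate_fraction_grid()
        assert len(pairs) <= 20
        assert all(a < b for a, b in pairs)

    def test_single_candidate_adjusted_equals_nominal(self):
        rng = np.random.default_rng(7)
        n = 30
        ids = [f"P{i}" for i in range(n)]
        vals = pd.Series(rng.random(n), index=ids)
        rec = _records(rng.exponential(10, n), [1] * n, ids=ids)
        res = surv.optimize_three_way_split(vals, rec, fraction_pairs=[(0.3, 0.7)])
        assert res.adjusted_p == pytest.approx(res.nominal_p)

    def test_detects_high_tertile_hazard(self):
        """Scaled-down simulation: the high-expression tertile has hazard
        ratio 3; the chosen split isolates a high group and reaches adjusted
        p < 0.05 at n = 90."""
        rng = np.random.default_rng(8)
        n = 90
        ids = [f"P{i}" for i in range(n)]
        vals = pd.Series(np.sort(rng.random(n)), index=ids)
        rate = np.where(np.arange(n) >= 60, 3.0 / 20.0, 1.0 / 20.0)
        times = rng.exponential(1 / rate)
        rec = _records(times, [1] * n, ids=ids)
        res = surv.optimize_three_way_split(vals, rec)
        assert res.adjusted_p < 0.05
        high = res.groups[res.groups == "high"].index
        assert set(high) <= set(ids[55:])

    def test_adjusted_at_least_nominal(self):
        rng = np.random.default_rng(9)
        n = 40
        ids = [f"P{i}" for i in range(n)]
        vals = pd.Series(rng.random(n), index=ids)
        rec = _records(rng.exponential(10, n), [1] * n, ids=ids)
        res = surv.optimize_three_way_split(vals, rec)
        assert (res.candidates["adjusted_p"] >= res.candidates["nominal_p"] - 1e-12).all()
        assert res.fractions[0] + res.fractions[1] + res.fractions[2] == pytest.approx(1.0)

    def test_no_valid_candidate_raises(self):
        ids = ["P0", "P1"]
        vals = pd.Series([0.1, 0.2], index=ids)
        rec = _records([1, 2], [1, 1], ids=ids)
        with pytest.raises(ValueError):
            surv.optimize_three_way_split(vals, rec, fraction_pairs=[(0.4, 0.6)])
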