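"""Statistical battery: Mann-Whitney, Pearson, ANOVA, duration split."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mrnquant as mq
from mrnquant.errors import InvalidParameterError, UndefinedCorrelationError


def exact_mw_p_by_enumeration(a, b):
    """Independent oracle: two-sided Mann-Whitney p by full enumeration.

    Enumerates every way the pooled observations could have been split into
    groups of sizes (n_a, n_b); p = fraction of splits whose U statistic is
    at least as extreme (in either tail) as the observed one.  Tie-free
    inputs only.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n_a, n_m = len(a), len(pooled)

    def u_stat(group_a, group_b):
        return sum(x > y for x in group_a for y in group_b) \
            + 0.5 * sum(x == y for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    mean_u = len(a) * len(b) / 2
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for idx in itertools.combinations(range(n_m), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n_m) if i not in idx]
        if abs(u_stat(ga, gb) - mean_u) >= dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestMannWhitney:
    def test_textbook_example_exact_third(self):
        res = mq.mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3, rel=1e-12)
        assert res.method.endswith("exact")
        # oracle: 6 equally likely rank assignments, 2 as extreme
        assert exact_mw_p_by_enumeration([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        res = mq.mann_whitney([1, 2, 3], [3, 2, 1])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            mq.mann_whitney([], [1.0])

    def test_mean_sem_attached(self):
        res = mq.mann_whitney([1, 2, 3], [4, 5, 6, 7])
        assert res.group_a_mean == pytest.approx(2.0)
        assert res.group_a_sem == pytest.approx(1.0 / math.sqrt(3))
        assert (res.n_a, res.n_b) == (3, 4)

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 3), (4, 4), (5, 5),
                                         (6, 6), (3, 6), (2, 5)])
    def test_exact_p_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(100 * n_a + n_b)
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = vals[:n_a], vals[n_a:]
            res = mq.mann_whitney(a, b)
            assert res.method.endswith("exact")
            assert res.p_value == pytest.approx(
                exact_mw_p_by_enumeration(a, b), rel=1e-9)

    def test_large_samples_use_asymptotic_with_ties(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=30).astype(float)
        b = rng.integers(1, 6, size=35).astype(float)
        res = mq.mann_whitney(a, b)
        assert res.method.endswith("asymptotic")
        assert 0 <= res.p_value <= 1

    def test_type_one_error_calibrated_under_null(self):
        # identical group distributions at the study's group sizes
        rng = np.random.default_rng(2024)
        rejections = 0
        n_runs = 1000
        for _ in range(n_runs):
            a = rng.normal(66.0, 3.5, size=35)
            b = rng.normal(66.0, 3.5, size=30)
            rejections += mq.mann_whitney(a, b).p_value < 0.05
        assert 0.03 <= rejections / n_runs <= 0.07


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = mq.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res = mq.pearson(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = mq.pearson([1, 2, 3], [1, 2, 4])
        # cov=1.5, sd_x=1, sd_y=sqrt(7/3) -> r = 1.5/sqrt(7/3)
        assert res.r == pytest.approx(1.5 / math.sqrt(7 / 3), rel=1e-9)
        assert res.r == pytest.approx(0.9820, abs=5e-5)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            mq.pearson([1, 1, 1], [1, 2, 3])

    def test_affine_invariance_up_to_slope_sign(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = mq.pearson(x, y)
        shifted = mq.pearson(3.2 * x - 7, y)
        flipped = mq.pearson(-2.0 * x + 1, y)
        assert shifted.r == pytest.approx(base.r, rel=1e-10)
        assert flipped.r == pytest.approx(-base.r, rel=1e-10)
        assert flipped.p_value == pytest.approx(base.p_value, rel=1e-9)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = mq.three_group_anova({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            mq.three_group_anova({"a": [1], "b": [2]})

    def test_f_equals_squared_t_on_the_distinct_pair(self):
        # one-way ANOVA restricted to the two distinct samples is t^2;
        # the three-group F with a duplicated sample stays finite and
        # significant but has no closed two-sample identity
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 12)
        from scipy import stats as sps
        t = sps.ttest_ind(a, b).statistic
        assert sps.f_oneway(a, b).statistic == pytest.approx(t ** 2, rel=1e-9)
        res = mq.three_group_anova({"a1": a, "a2": a, "b": b})
        assert res.f_statistic > 0
        assert res.posthoc["a1_vs_a2"] > 0.9

    def test_shifted_group_dominates_posthoc(self):
        rng = np.random.default_rng(77)
        hits = 0
        n_runs = 50
        for _ in range(n_runs):
            base = {"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
                    "c": rng.normal(4, 1, 15)}
            res = mq.three_group_anova(base)
            ok = (res.posthoc["a_vs_c"] < 0.05
                  and res.posthoc["b_vs_c"] < 0.05
                  and res.posthoc["a_vs_b"] >= 0.05)
            hits += ok
        assert hits >= 0.9 * n_runs


class TestDurationSplitAndBattery:
    def _clinical(self):
        return pd.DataFrame({
            "participant_id": ["c1", "c2", "c3", "h1"],
            "group": ["case", "case", "case", "control"],
            "duration": [35.0, 36.0, 120.0, np.nan],
        })

    def test_boundary_at_36_months(self):
        labels = mq.duration_split(self._clinical())
        assert labels.tolist() == ["case_short_duration", "case_long_duration",
                                   "case_long_duration", "control"]

    def test_missing_case_duration_raises(self):
        bad = self._clinical()
        bad.loc[0, "duration"] = np.nan
        with pytest.raises(InvalidParameterError):
            mq.duration_split(bad)

    def test_battery_shape_and_content(self, small_protocol):
        cfg = mq.CohortConfig(n_case=6, n_control=5, center_jitter_mm=0.0)
        frames = mq.simulate_measure_aggregate(small_protocol, cfg, seed=3)
        res = mq.analysis_battery(frames["regions"], frames["clinical"])
        # 4 markers x 2 regions case-vs-control
        assert len(res.group_comparisons) == 8
        # 2 groups x 4 markers proximal-vs-distal, same for sides
        assert len(res.location_comparisons) == 8
        assert len(res.side_comparisons) == 8
        assert len(res.demographic_comparisons) == 3
        df = res.to_frame()
        assert set(df["analysis"]) >= {"group", "location", "side",
                                       "demographic", "correlation"}
        assert df["p_value"].dropna().between(0, 1).all()
        assert res.n_tests == sum(
            (df["analysis"] == k).sum()
            for k in ("group", "location", "side", "demographic",
                      "correlation", "anova"))
        payload = res.to_dict()
        assert payload["n_tests"] == res.n_tests
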