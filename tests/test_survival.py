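"""Marker distributions, stratification, KM/log-rank, longitudinal rule."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from pepmrd import (
    MarkerSurvival,
    MarkerThreshold,
    PeakMatrix,
    SubjectRecord,
    km_estimate,
    log_rank,
    marker_by_group,
    monitor_longitudinal,
    simulate_survival,
    stratify,
)


def naive_logrank_chi2(times, events, member):
    """Independent log-rank reference: explicit risk-set loop.

    chi2 = (sum_t (O1 - E1))^2 / sum_t V, with the standard hypergeometric
    variance at each distinct event time (simultaneous-death convention).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    member = np.asarray(member, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & member).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & member).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


def _matrix(ids, marker_vals, extra=0.9):
    vals = np.asarray(marker_vals, float)
    rel = np.column_stack([vals, 1 - vals])
    return PeakMatrix(np.array([4625.0, 8000.0]), list(ids), rel)


class TestMarkerByGroup:
    def test_group_medians_follow_remission_grade(self, cohort):
        _, records, truth, matrix = cohort
        summary, pairwise = marker_by_group(matrix, records)
        med = summary["median"]
        assert med["newly_diagnosed"] >= med["HCR"] >= med["MR"]
        assert pairwise.loc["newly_diagnosed", "healthy"] < 0.05

    def test_absent_marker_bin_error_names_nearest(self):
        m = PeakMatrix(np.array([3000.0, 8000.0]), ["a"], np.array([[0.4, 0.6]]))
        with pytest.raises(KeyError, match="3000"):
            marker_by_group(m, [SubjectRecord("a", "healthy")], MarkerThreshold(4625.0))

    def test_singleton_group_quartiles_collapse_and_tests_unavailable(self):
        m = _matrix(["a", "b", "c"], [0.01, 0.03, 0.05])
        records = [
            SubjectRecord("a", "healthy"),
            SubjectRecord("b", "healthy"),
            SubjectRecord("c", "newly_diagnosed"),
        ]
        summary, pairwise = marker_by_group(m, records)
        assert summary.loc["newly_diagnosed", "q25"] == 0.05
        assert summary.loc["newly_diagnosed", "q75"] == 0.05
        assert np.isnan(pairwise.loc["healthy", "newly_diagnosed"])


class TestStratify:
    def test_low_high_assignment(self):
        m = _matrix(["a", "b"], [0.01, 0.03])
        recs = [SubjectRecord("a", "newly_diagnosed"), SubjectRecord("b", "newly_diagnosed")]
        s = stratify(m, recs)
        assert s["a"] == "low" and s["b"] == "high"

    def test_exact_boundary_follows_rule(self):
        m = _matrix(["a"], [0.02])
        recs = [SubjectRecord("a", "newly_diagnosed")]
        assert stratify(m, recs)["a"] == "high"
        low_rule = MarkerThreshold(boundary_rule="boundary_to_low")
        assert stratify(m, recs, low_rule)["a"] == "low"

    def test_high_stratum_has_more_events_under_coupling(self):
        """Generative check at n=200: positive survival coupling makes the
        high-marker stratum accumulate more deaths within follow-up."""
        n = 200
        rng = np.random.default_rng(10)
        marker = np.r_[rng.uniform(0.001, 0.015, n), rng.uniform(0.03, 0.08, n)]
        ids = [f"s{i}" for i in range(2 * n)]
        recs = [SubjectRecord(s, "newly_diagnosed") for s in ids]
        truth = dict(zip(ids, marker))
        recs = simulate_survival(recs, truth, coupling=60.0, censor_rate=0.3, seed=11)
        m = _matrix(ids, marker)
        strata = stratify(m, recs)
        events = {"low": [], "high": []}
        for r in recs:
            events[strata[r.subject_id]].append(bool(r.event))
        assert np.mean(events["high"]) > np.mean(events["low"])


class TestKM:
    def test_no_censoring_equals_empirical_survival(self, rng):
        """Product-limit == empirical survivor fraction when nothing is
        censored (oracle over random event-time sets)."""
        for _ in range(50):
            n = int(rng.integers(1, 40))
            times = np.round(rng.exponential(12, n), 1)
            curve = km_estimate(times, np.ones(n, bool))
            for t in np.unique(times):
                assert curve.evaluate(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_three_events_no_censoring(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert curve.evaluate(2.5) == pytest.approx(1 / 3)

    def test_all_censored_flat_at_one(self):
        curve = km_estimate([5.0, 8.0], [False, False])
        assert curve.evaluate(100.0) == 1.0
        assert curve.times.size == 0

    def test_censored_subject_leaves_risk_set(self):
        # (5 censored, 10, 10): S(10) = 1 x (1 - 2/2) = 0
        curve = km_estimate([5.0, 10.0, 10.0], [False, True, True])
        assert curve.evaluate(10.0) == pytest.approx(0.0)
        assert curve.at_risk.tolist() == [2.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    def test_curve_invariants(self, rng):
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30).astype(bool)
        events[:2] = True
        curve = km_estimate(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all(np.diff(curve.at_risk) < 0)
        assert curve.survival[0] <= 1.0


class TestLogRank:
    def test_identical_groups_chi2_zero(self):
        times = [3.0, 6.0, 9.0, 3.0, 6.0, 9.0]
        events = [True] * 6
        labels = ["a"] * 3 + ["b"] * 3
        res = log_rank(times, events, labels)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_reference_over_label_permutations(self, rng):
        """The statistic agrees with an explicit risk-set-loop reference on
        random small inputs, across many group labelings (n <= 12)."""
        checked = 0
        for trial in range(12):
            n = int(rng.integers(6, 13))
            times = np.round(rng.exponential(10, n), 1) + 0.1
            events = rng.integers(0, 2, n).astype(bool)
            events[:2] = True
            for _ in range(10):
                member = rng.integers(0, 2, n).astype(bool)
                if member.all() or not member.any():
                    continue
                ours = log_rank(times, events, member.astype(int)).chi_square
                ref = naive_logrank_chi2(times, events, member)
                assert ours == pytest.approx(ref, rel=1e-6, abs=1e-9)
                checked += 1
        assert checked > 50

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError, match="two"):
            log_rank([1.0, 2.0], [True, True], ["a", "a"])

    def test_power_under_strong_separation(self, rng):
        """n=100 per arm with a large hazard ratio: p < 0.001."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            a = r.exponential(20, 100)
            b = r.exponential(4, 100)
            res = log_rank(np.r_[a, b], np.ones(200, bool), [0] * 100 + [1] * 100)
            assert res.p_value < 0.001

    def test_null_p_values_roughly_uniform(self):
        """Under no survival difference the log-rank p-value is uniform
        (KS check over replicates)."""
        ps = []
        for seed in range(300):
            r = np.random.default_rng(20_000 + seed)
            t = r.exponential(12, 24)
            e = r.uniform(size=24) > 0.25
            if not e.any():
                continue
            ps.append(log_rank(t, e, [0] * 12 + [1] * 12).p_value)
        assert sstats.kstest(ps, "uniform").pvalue > 0.01


class TestLongitudinal:
    def test_below_cutoff_never_flags(self):
        flags = monitor_longitudinal({"p": [(0, 0.005), (1, 0.004), (2, 0.006)]})
        assert flags == {"p": False}

    def test_two_rises_above_cutoff_flags(self):
        flags = monitor_longitudinal({"p": [(0, 0.015), (1, 0.025), (2, 0.035)]})
        assert flags == {"p": True}

    def test_constant_series_above_cutoff_no_flag(self):
        flags = monitor_longitudinal({"p": [(0, 0.05), (1, 0.05), (2, 0.05)]})
        assert flags == {"p": False}

    def test_unordered_timestamps_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            monitor_longitudinal({"p": [(1, 0.01), (0, 0.02)]})

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 time points"):
            monitor_longitudinal({"p": [(0, 0.01)]})


class TestMarkerSurvivalModel:
    def test_recovers_planted_direction(self, cohort):
        """High measured marker at diagnosis -> worse survival, given the
        generator's positive coupling."""
        _, records, truth, matrix = cohort
        leukemia = [r for r in records if r.survival_months is not None]
        fitted = MarkerSurvival.from_cohort(matrix, leukemia).fit()
        assert set(fitted.curves) == {"low", "high"}
        t = float(np.median([r.survival_months for r in leukemia]))
        assert fitted.curves["high"].evaluate(t) <= fitted.curves["low"].evaluate(t) + 0.1
        assert "log-rank" in fitted.summary()

    def test_direct_construction_and_two_year_rates(self):
        # 18 subjects, 9 deaths before 24 months; 15 subjects, 11 deaths
        times = [12.0] * 9 + [29.0] * 9 + [7.0] * 11 + [29.0] * 4
        events = [True] * 9 + [False] * 9 + [True] * 11 + [False] * 4
        strata = ["low"] * 18 + ["high"] * 15
        fitted = MarkerSurvival(times, events, strata).fit()
        rates = fitted.survival_at(24.0)
        assert rates["low"] == pytest.approx(0.5, abs=1e-9)
        assert rates["high"] == pytest.approx(4 / 15, abs=1e-9)
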