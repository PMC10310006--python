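"""Survival-core tests: Cox loss, c-index, Kaplan-Meier, log-rank, tertiles."""

import numpy as np
import pytest

from conftest import random_records
from dalan.survival import (
    KaplanMeierEstimate, SurvivalRecord, RiskPrediction,
    cox_partial_log_likelihood_loss, concordance_index, kaplan_meier,
    logrank_test, normalize_risks, stratify_by_risk,
)


def brute_force_cindex(risks, records, tie_value=0.0):
    """Independent O(n^2) pair enumeration of the concordance formula."""
    num = den = 0.0
    n = len(records)
    for i in range(n):
        if records[i].event != 1:
            continue
        for j in range(n):
            if records[j].time > records[i].time:
                den += 1
                if risks[j] < risks[i]:
                    num += 1
                elif risks[j] == risks[i]:
                    num += tie_value
    return num / den


class TestCoxLoss:
    def test_single_event_is_zero(self):
        # the lone subject's term h - log exp(h) vanishes for any h
        for h in (-3.0, 0.0, 7.5):
            assert cox_partial_log_likelihood_loss([h], [SurvivalRecord(2.0, 1)]) == pytest.approx(0.0)

    @pytest.mark.parametrize("delta", np.linspace(-10, 10, 21))
    def test_two_sample_closed_form(self, delta):
        # events at t1 < t2 with hazards h1, h2: loss = log(1 + exp(h2 - h1))
        h1 = 0.7
        recs = [SurvivalRecord(1.0, 1), SurvivalRecord(2.0, 1)]
        loss = cox_partial_log_likelihood_loss([h1, h1 + delta], recs, reduction="sum")
        assert loss == pytest.approx(np.log1p(np.exp(delta)), rel=1e-9, abs=1e-12)

    def test_shift_invariance(self, rng):
        recs = random_records(rng, 40)
        h = rng.normal(size=40)
        base = cox_partial_log_likelihood_loss(h, recs)
        for c in (-50.0, 3.7, 120.0):
            shifted = cox_partial_log_likelihood_loss(h + c, recs)
            assert shifted == pytest.approx(base, rel=1e-9)

    def test_all_censored_warns_and_returns_zero(self):
        recs = [SurvivalRecord(1.0, 0), SurvivalRecord(2.0, 0)]
        with pytest.warns(UserWarning):
            assert cox_partial_log_likelihood_loss([0.3, -1.0], recs) == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            cox_partial_log_likelihood_loss([], [])

    def test_tied_times_share_risk_sets(self):
        # with t1 == t2 (both events) each subject's risk set contains both
        recs = [SurvivalRecord(3.0, 1), SurvivalRecord(3.0, 1)]
        h = np.array([0.2, 1.4])
        expect = -sum(h[i] - np.log(np.exp(h).sum()) for i in range(2))
        got = cox_partial_log_likelihood_loss(h, recs, reduction="sum")
        assert got == pytest.approx(expect, rel=1e-12)

    def test_mean_reduction_divides_by_events(self, rng):
        recs = random_records(rng, 25)
        h = rng.normal(size=25)
        n_events = sum(r.event for r in recs)
        s = cox_partial_log_likelihood_loss(h, recs, reduction="sum")
        m = cox_partial_log_likelihood_loss(h, recs, reduction="mean")
        assert m == pytest.approx(s / n_events, rel=1e-12)


class TestConcordance:
    def test_perfect_anti_ordering(self):
        recs = [SurvivalRecord(t, 1) for t in (1.0, 2.0, 3.0, 4.0)]
        risks = [4.0, 3.0, 2.0, 1.0]       # higher risk => shorter time
        assert concordance_index(risks, recs) == 1.0

    def test_identical_risks_strict_vs_half(self):
        recs = [SurvivalRecord(t, 1) for t in (1.0, 2.0, 3.0)]
        assert concordance_index([0.5] * 3, recs, ties="strict") == 0.0
        assert concordance_index([0.5] * 3, recs, ties="half") == 0.5

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 30))
        recs = random_records(rng, n)
        risks = rng.normal(size=n)
        for ties, tv in (("strict", 0.0), ("half", 0.5)):
            assert concordance_index(risks, recs, ties=ties) == pytest.approx(
                brute_force_cindex(risks, recs, tv), abs=1e-12)

    def test_matches_standard_package_with_half_ties(self, rng):
        sksurv = pytest.importorskip("sksurv.metrics")
        recs = random_records(rng, 80)
        risks = rng.normal(size=80)
        times = np.array([r.time for r in recs])
        events = np.array([r.event for r in recs]).astype(bool)
        ours = concordance_index(risks, recs, ties="half")
        ref = sksurv.concordance_index_censored(events, times, np.asarray(risks))[0]
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_independent_risks_near_half(self):
        rng = np.random.default_rng(7)
        recs = random_records(rng, 2000, censor_p=0.3)
        risks = rng.normal(size=2000)
        assert concordance_index(risks, recs, ties="half") == pytest.approx(0.5, abs=0.03)

    def test_no_admissible_pairs_errors(self):
        recs = [SurvivalRecord(5.0, 0), SurvivalRecord(1.0, 0)]
        with pytest.raises(ValueError, match="admissible"):
            concordance_index([0.1, 0.2], recs)


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        est = kaplan_meier([SurvivalRecord(t, 0) for t in (1.0, 2.0, 5.0)])
        assert np.all(est.survival == 1.0)
        assert np.isnan(est.median)

    def test_three_events_product_limit(self):
        est = kaplan_meier([SurvivalRecord(t, 1) for t in (1.0, 2.0, 3.0)])
        np.testing.assert_allclose(est.survival_at([0.5, 1.5, 2.5, 3.5]),
                                   [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert est.median == pytest.approx(2.0)

    def test_single_event(self):
        est = kaplan_meier([SurvivalRecord(5.0, 1)])
        assert est.survival_at(4.9) == pytest.approx(1.0)
        assert est.survival_at(5.0) == pytest.approx(0.0)
        assert est.median == pytest.approx(5.0)

    @pytest.mark.parametrize("times,events,grid,expected,median", [
        # hand product-limit: censored subject between events
        ((1, 2, 3), (1, 0, 1), (1.5, 2.5, 3.5), (2 / 3, 2 / 3, 0.0), 3.0),
        # tie at an event time: two drop at once
        ((2, 2, 4), (1, 1, 1), (1.0, 3.0, 4.5), (1.0, 1 / 3, 0.0), 2.0),
        # censoring after last event leaves plateau above zero
        ((1, 2, 5), (1, 1, 0), (1.5, 2.5, 6.0), (2 / 3, 1 / 3, 1 / 3), 2.0),
        # all events, four subjects
        ((1, 2, 3, 4), (1, 1, 1, 1), (1.5, 2.5, 3.5), (0.75, 0.5, 0.25), 2.0),
        # first subject censored: risk set shrinks without a drop
        ((1, 2), (0, 1), (1.5, 2.5), (1.0, 0.0), 2.0),
    ])
    def test_hand_computed_fixtures(self, times, events, grid, expected, median):
        recs = [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]
        est = kaplan_meier(recs)
        np.testing.assert_allclose(est.survival_at(list(grid)), expected, atol=1e-12)
        assert est.median == pytest.approx(median)

    def test_monotone_non_increasing(self, rng):
        est = kaplan_meier(random_records(rng, 100))
        assert np.all(np.diff(est.survival) <= 1e-12)
        assert est.survival[0] <= 1.0 + 1e-12


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = [SurvivalRecord(t, 1) for t in (1.0, 2.0, 3.0, 4.0)]
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_exponentials_significant(self):
        rng = np.random.default_rng(3)
        g1 = [SurvivalRecord(float(t), 1) for t in rng.exponential(1.0, 100)]
        g2 = [SurvivalRecord(float(t), 1) for t in rng.exponential(0.1, 100)]
        assert logrank_test([g1, g2]).p_value < 1e-3

    def test_agrees_with_reference_implementation(self, rng):
        from lifelines.statistics import logrank_test as ll_two_sample
        g1 = random_records(rng, 40)
        g2 = random_records(rng, 55)
        ours = logrank_test([g1, g2])
        t1, e1 = np.array([[r.time, r.event] for r in g1]).T
        t2, e2 = np.array([[r.time, r.event] for r in g2]).T
        ref = ll_two_sample(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert ours.statistic == pytest.approx(float(ref.test_statistic), rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="zero subjects"):
            logrank_test([[SurvivalRecord(1.0, 1)], []])


class TestStratification:
    def test_three_risks_map_to_tertiles(self):
        assert stratify_by_risk([-1.0, 0.0, 1.0]) == ["low", "mid", "high"]

    def test_nine_distinct_equal_split(self, rng):
        risks = rng.permutation(9).astype(float)
        labels = np.array(stratify_by_risk(list(risks)))
        assert sorted((labels == g).sum() for g in ("low", "mid", "high")) == [3, 3, 3]
        # group boundaries respect ordering
        assert risks[labels == "low"].max() < risks[labels == "mid"].min()
        assert risks[labels == "mid"].max() < risks[labels == "high"].min()

    def test_ties_at_cut_resolved_by_position(self):
        # four equal risks among six subjects: stable sort keeps input order
        risks = [0.0, 1.0, 1.0, 1.0, 1.0, 2.0]
        labels = stratify_by_risk(risks)
        assert labels == ["low", "low", "mid", "mid", "high", "high"]

    def test_affine_invariance(self, rng):
        risks = rng.normal(size=31)
        base = stratify_by_risk(list(risks))
        for a, b in ((2.5, -3.0), (0.1, 100.0)):
            assert stratify_by_risk(list(a * risks + b)) == base

    def test_normalization_zero_mean_unit_sd(self, rng):
        z = normalize_risks(rng.normal(2.0, 5.0, size=200))
        assert abs(z.mean()) < 1e-6
        assert abs(z.std() - 1.0) < 1e-6

    def test_fills_prediction_objects(self):
        preds = [RiskPrediction(f"p{i}", float(i)) for i in range(6)]
        stratify_by_risk(preds)
        assert all(p.normalized_risk is not None and p.risk_group is not None
                   for p in preds)

    def test_too_few_patients_errors(self):
        with pytest.raises(ValueError):
            stratify_by_risk([1.0, 2.0])
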