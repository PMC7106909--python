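"""ROC/AUC, logistic response models, BH adjustment, stratification, Cox/KM."""

import numpy as np
import pytest

from tvburden.evaluate import (
    PatientRecord,
    bh_adjust,
    classification_concordance,
    classify_high_low,
    fit_response_model,
    fit_survival,
    mann_whitney_auc,
    roc_auc,
    threshold_sweep,
)


class TestRoc:
    def test_perfect_and_reversed_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)
        assert roc_auc([4, 3, 2, 1], [0, 0, 1, 1]).auc == pytest.approx(0.0)

    def test_ties_count_half(self):
        # one responder ties one non-responder: AUC = (1 + 0.5)/2 pairs... by
        # hand: pairs (5>1)=1, (5 vs 5)=0.5, (3>1)=1, (3<5)=0 -> 2.5/4
        auc = roc_auc([1, 5, 5, 3], [0, 0, 1, 1]).auc
        assert auc == pytest.approx(0.625)
        assert mann_whitney_auc([1, 5, 5, 3], [0, 0, 1, 1]) == pytest.approx(0.625)

    def test_trapezoid_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 80))
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestLogistic:
    @staticmethod
    def simulate(n, beta0, beta1, seed, therapy_offset=None):
        rng = np.random.default_rng(seed)
        burden = rng.lognormal(np.log(100), 1.0, size=n)
        eta = beta0 + beta1 * np.log2(burden + 1)
        therapy = None
        if therapy_offset is not None:
            therapy = np.where(rng.random(n) < 0.5, "aCTLA4", "aPD1")
            eta = eta + therapy_offset * (therapy == "aCTLA4")
        response = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return burden, response, therapy

    def test_recovers_slope_on_large_sample(self):
        burden, response, _ = self.simulate(4000, -3.0, 0.5, seed=1)
        fit = fit_response_model(burden, response)
        assert fit.slope == pytest.approx(0.5, abs=0.1)
        assert fit.p_value < 1e-6
        assert fit.response_prob_q75 > fit.response_prob_q25

    def test_therapy_indicator_recovered(self):
        burden, response, therapy = self.simulate(4000, -3.0, 0.5, seed=2,
                                                  therapy_offset=-1.0)
        fit = fit_response_model(burden, response, therapy)
        assert fit.therapy_offset == pytest.approx(-1.0, abs=0.25)

    def test_odds_increase_percentage_formula(self):
        burden, response, _ = self.simulate(500, -3.0, 0.5, seed=3)
        fit = fit_response_model(burden, response)
        assert fit.odds_increase_pct == pytest.approx(
            (np.exp(fit.slope) - 1) * 100
        )
        fit.slope = np.log(2.208)
        assert fit.odds_increase_pct == pytest.approx(120.8)

    def test_quartile_probabilities_marginalize_over_therapy_mix(self):
        burden = np.linspace(1, 100, 40)
        response = (burden > 40).astype(int)
        therapy = np.array(["aPD1", "aCTLA4"] * 20)
        fit = fit_response_model(burden, response, therapy)
        assert 0.0 <= fit.response_prob_q25 <= fit.response_prob_q75 <= 1.0

    def test_perfect_separation_is_flagged_not_silent(self):
        burden = np.array([1.0] * 10 + [1000.0] * 10)
        response = np.array([0] * 10 + [1] * 10)
        fit = fit_response_model(burden, response)
        assert fit.separation_flag

    def test_small_sample_and_combination_therapy_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            fit_response_model([1, 2, 3], [0, 1, 0])
        burden, response, _ = self.simulate(20, -3.0, 0.5, seed=4)
        with pytest.raises(ValueError, match="combination"):
            fit_response_model(burden, response, ["combination"] * 20)


class TestBhAdjust:
    @staticmethod
    def brute_force_bh(p):
        """Step-up oracle: q_i = min over j>=rank(i) of p_(j) * m / j, capped at 1."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for k in range(m - 1, -1, -1):
            running = min(running, p[order[k]] * m / (k + 1))
            q[order[k]] = running
        return q

    def test_hand_fixture(self):
        p = [0.01, 0.04, 0.03, 0.50]
        # sorted: .01 .03 .04 .5 -> raw .04, .06, .0533.., .5 -> step-up
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.0533333333, 0.0533333333, 0.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_monotone_and_bounded(self):
        p = np.sort(np.random.default_rng(6).random(25))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12) and np.all(q <= 1) and np.all(q >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestHighLow:
    def test_eightieth_percentile_on_one_to_ten(self):
        labels = classify_high_low(np.arange(1, 11), 80)  # cut = 8.2
        assert labels.tolist() == [0] * 8 + [1, 1]

    def test_strict_exceedance_means_all_equal_gives_no_high(self):
        assert classify_high_low([5, 5, 5, 5], 80).sum() == 0

    def test_boundary_value_is_low(self):
        # percentile of [0..4] at 80 is 3.2; value 3.2 itself must be low
        assert classify_high_low([0, 1, 2, 3.2, 4], 80).tolist() == [0, 0, 0, 0, 1]

    def test_concordant_for_monotone_transform_discordant_when_reversed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = classification_concordance(a, np.log(a + 1), [25, 50, 80])
        assert all(v == 0.0 for v in out.values())
        out = classification_concordance(a, a[::-1].copy(), [50])
        assert out[50.0] == 1.0


def make_cohort(n, hr, seed, horizon=None, censor_rate=0.2):
    """Exponential survival with hazard ratio `hr` for the top-20% stratum."""
    rng = np.random.default_rng(seed)
    burden = rng.lognormal(np.log(100), 1.0, size=n)
    high = classify_high_low(burden, 80)
    lam = 1 / 1500 * np.where(high == 1, hr, 1.0)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / (censor_rate / 1500))
    time = np.minimum(t, c)
    event = t <= c
    recs = [
        PatientRecord(f"P{i}", "melanoma", os_time=float(time[i]),
                      os_event=bool(event[i]))
        for i in range(n)
    ]
    return recs, high, burden


class TestSurvival:
    def test_recovers_hazard_ratio(self):
        recs, high, _ = make_cohort(2000, 2.0, seed=7)
        fit = fit_survival(recs, high)
        assert not fit.flagged
        assert fit.ci_lower < 2.0 < fit.ci_upper
        assert fit.hazard_ratio == pytest.approx(2.0, rel=0.2)
        assert fit.p_value < 1e-4

    def test_km_curves_and_at_risk_tables_present(self):
        recs, high, _ = make_cohort(100, 2.0, seed=8)
        fit = fit_survival(recs, high)
        assert set(fit.km_curves) == {"high", "low"}
        for name, table in fit.at_risk.items():
            assert table.iloc[0] == {"high": fit.n_high, "low": fit.n_low}[name]
            sf = fit.km_curves[name].to_numpy().ravel()
            assert np.all(np.diff(sf) <= 1e-12)  # survival is non-increasing

    def test_zero_event_stratum_is_flagged_with_nan_hr(self):
        recs = [
            PatientRecord(f"P{i}", "melanoma", os_time=100.0 + i, os_event=(i < 4))
            for i in range(8)
        ]
        high = [0] * 4 + [1] * 4  # all events in the low stratum
        fit = fit_survival(recs, high)
        assert fit.flagged and np.isnan(fit.hazard_ratio)

    def test_horizon_applies_administrative_censoring(self):
        recs = [
            PatientRecord("A", "m", os_time=3000.0, os_event=True),
            PatientRecord("B", "m", os_time=100.0, os_event=True),
            PatientRecord("C", "m", os_time=3000.0, os_event=True),
            PatientRecord("D", "m", os_time=200.0, os_event=False),
        ]
        fit = fit_survival(recs, [1, 1, 0, 0], horizon_days=2885.0)
        low = fit.km_curves["low"]
        assert low.index.max() <= 2885.0
        assert low.to_numpy().ravel()[-1] == 1.0  # censored-only stratum

    def test_threshold_sweep_flags_degenerate_points(self):
        recs, _, burden = make_cohort(60, 2.0, seed=9)
        df = threshold_sweep(recs, burden, [20, 50, 80, 99])
        assert list(df["percentile"]) == [20.0, 50.0, 80.0, 99.0]
        assert df.loc[df["percentile"] == 99.0, "n_high"].iloc[0] <= 1
        with pytest.raises(ValueError):
            threshold_sweep(recs, burden, [0])


class TestPatientRecord:
    def test_invalid_therapy_and_time_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord("P", "melanoma", therapy="chemo")
        with pytest.raises(ValueError):
            PatientRecord("P", "melanoma", os_time=0.0)
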