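"""Unit tests of the derived behavioral scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psycop.scoring import (
    LightCycle, SprtConfig, circadian_profile, instantaneous_frequency,
    mean_phase_rate, nocturnality_score, place_preference_score, ppi_percent,
    preference_score, serial_reversal_auc, spontaneous_alternation_rate,
    sprt_trials_to_criterion, success_rate, zscore_profile,
)


@pytest.mark.parametrize("a,b,expected", [
    (60, 20, 0.5),
    (15, 15, 0.0),
    (0, 7, -1.0),
    (7, 0, 1.0),
])
def test_preference_score_formula(a, b, expected):
    assert preference_score(a, b) == pytest.approx(expected)


def test_preference_score_no_observations_is_missing_not_zero():
    assert math.isnan(preference_score(0, 0))


@pytest.mark.parametrize("correct,incorrect,expected", [
    (25, 75, 0.0),          # uniform chooser over 1 correct vs 3 wrong corners
    (10, 0, 1.0),
    (50, 50, 0.5),          # (50 - 50/3) / (50 + 50/3)
])
def test_place_preference_chance_weighting(correct, incorrect, expected):
    assert place_preference_score(correct, incorrect) == pytest.approx(expected)


def test_place_preference_zero_mean_under_uniform_choice(rng):
    """A mouse choosing corners uniformly must score 0 in expectation."""
    n = rng.poisson(100, size=10_000) + 1
    correct = rng.binomial(n, 0.25)
    scores = np.array([place_preference_score(c, t - c) for c, t in zip(correct, n)])
    assert abs(np.nanmean(scores)) < 0.02


class TestSprt:
    cfg = SprtConfig(p0=0.25, p1=0.75, alpha=0.05, beta=0.05)

    def test_all_correct_crosses_at_trial_three(self):
        # increment ln 3 per correct trial; boundary ln 19 ~ 2.944 -> 3 trials
        n, censored = sprt_trials_to_criterion([True] * 10, self.cfg)
        assert (n, censored) == (3, False)

    def test_alternating_increments_cancel(self):
        seq = [True, False] * 20
        n, censored = sprt_trials_to_criterion(seq, self.cfg)
        assert (n, censored) == (40, True)

    def test_all_incorrect_is_censored(self):
        n, censored = sprt_trials_to_criterion([False] * 25, self.cfg)
        assert (n, censored) == (25, True)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sprt_trials_to_criterion([], self.cfg)

    @pytest.mark.parametrize("kw", [dict(p0=0.8, p1=0.5), dict(alpha=0.7),
                                    dict(beta=0.0), dict(p0=0.0)])
    def test_invalid_config(self, kw):
        with pytest.raises(ValueError):
            SprtConfig(**kw)

    def test_monotone_in_success_probability(self, rng):
        """Median trials-to-criterion decreases with the true success rate."""
        medians = []
        for p in (0.4, 0.6, 0.8):
            ns = [sprt_trials_to_criterion(rng.random(400) < p, self.cfg)[0]
                  for _ in range(200)]
            medians.append(np.median(ns))
        assert medians[0] > medians[1] > medians[2]


class TestSerialReversalAuc:
    def test_trapezoid_hand_case(self):
        assert serial_reversal_auc([100, 80, 60, 40, 20]) == pytest.approx(240.0)

    def test_constant_curve(self):
        assert serial_reversal_auc([37, 37]) == pytest.approx(37.0)

    def test_order_sensitivity_for_three_phases(self):
        assert serial_reversal_auc([20, 100]) == serial_reversal_auc([100, 20]) == 60
        assert serial_reversal_auc([20, 100, 20]) == pytest.approx(120.0)
        assert serial_reversal_auc([100, 20, 20]) == pytest.approx(80.0)

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            serial_reversal_auc([50])


def test_success_and_rewarded_rates():
    assert success_rate([True] * 30 + [False] * 10) == pytest.approx(0.75)
    assert math.isnan(success_rate([]))


def test_mean_rate_averages_phases_not_pooled_trials():
    # 10 trials at 1.0 and 90 trials at 0.0: pooled = 0.1, phase mean = 0.5
    assert mean_phase_rate([1.0, 0.0]) == pytest.approx(0.5)


@pytest.mark.parametrize("arms,expected", [
    (list("ABCABC"), 1.0),
    (list("ABAB"), 0.0),
    (list("ABCB"), 0.5),   # windows ABC (alternation), BCB (repeat)
])
def test_spontaneous_alternation(arms, expected):
    assert spontaneous_alternation_rate(arms) == pytest.approx(expected)


def test_spontaneous_alternation_too_short_is_missing():
    assert math.isnan(spontaneous_alternation_rate(["A", "B"]))


class TestActivity:
    def test_constant_spacing(self):
        t = np.arange(4) * 3600.0
        assert instantaneous_frequency(t) == pytest.approx(1.0)

    def test_harmonic_not_arithmetic(self):
        # intervals 0.5 h and 1.5 h -> mean(2, 2/3) = 4/3, not 1/mean = 1
        t = np.array([0.0, 0.5, 2.0]) * 3600.0
        assert instantaneous_frequency(t) == pytest.approx(4.0 / 3.0)

    def test_single_visit_missing(self):
        assert math.isnan(instantaneous_frequency([100.0]))

    def test_counts_per_hour_variant(self):
        t = np.array([0.0, 0.5, 2.0]) * 3600.0
        assert instantaneous_frequency(t, method="counts") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            instantaneous_frequency(t, method="bogus")

    def test_circadian_profile_bins(self):
        # visits every 30 min within hour 2 only
        t = (2.0 + np.arange(4) * 0.5) * 3600.0
        prof = circadian_profile(t)
        assert prof[2] == pytest.approx(2.0)
        assert np.isnan(prof[5])

    def test_translation_by_whole_days_invariant(self, rng):
        t = np.sort(rng.uniform(0, 3 * 86400, 300))
        shift = 2 * 86400.0
        assert instantaneous_frequency(t + shift) == pytest.approx(
            instantaneous_frequency(t))
        assert nocturnality_score(t + shift) == pytest.approx(nocturnality_score(t))


class TestNocturnality:
    lc = LightCycle(light_on=0.0, light_hours=12.0)

    def test_all_dark_phase(self):
        t = (np.array([13.0, 15.0, 20.0])) * 3600.0
        assert nocturnality_score(t, self.lc) == pytest.approx(1.0)

    def test_balanced(self):
        t = np.array([1.0, 13.0]) * 3600.0
        assert nocturnality_score(t, self.lc) == pytest.approx(0.0)

    def test_thirty_night_ten_day(self):
        t = np.concatenate([np.linspace(13, 23, 30), np.linspace(1, 11, 10)]) * 3600.0
        assert nocturnality_score(t, self.lc) == pytest.approx(0.5)

    def test_no_visits_missing(self):
        assert math.isnan(nocturnality_score([], self.lc))


@pytest.mark.parametrize("base,pp,expected", [
    (100.0, 40.0, 60.0),
    (80.0, 80.0, 0.0),
    (100.0, 120.0, -20.0),   # facilitation is negative
])
def test_ppi_percent(base, pp, expected):
    assert ppi_percent([base] * 5, [pp] * 5) == pytest.approx(expected)


def test_ppi_zero_baseline_missing():
    assert math.isnan(ppi_percent([0.0, 0.0], [1.0]))


@given(a=st.integers(0, 1000), b=st.integers(0, 1000))
@settings(max_examples=200, deadline=None)
def test_preference_scores_bounded(a, b):
    for fn in (preference_score, place_preference_score):
        s = fn(a, b)
        assert math.isnan(s) or -1.0 <= s <= 1.0


class TestZscoreProfile:
    def _toy(self):
        mat = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "y": [10.0, 10.0, 14.0, 14.0]},
            index=["m1", "m2", "m3", "m4"])
        design = pd.DataFrame(
            {"S": ["placebo", "placebo", "spironolactone", "spironolactone"],
             "A": ["placebo"] * 4},
            index=mat.index)
        return mat, design

    def test_reference_row_is_zero(self):
        mat, design = self._toy()
        z = zscore_profile(mat, design)
        assert np.allclose(z.loc["placebo/placebo"], 0.0)

    def test_hand_computation(self):
        mat, design = self._toy()
        z = zscore_profile(mat, design)
        # x: mean 2.5, sd ~1.2910 -> group means (+/-1)/sd; difference = 2/sd
        sd_x = mat["x"].std(ddof=1)
        assert z.loc["spironolactone/placebo", "x"] == pytest.approx(2.0 / sd_x)
        sd_y = mat["y"].std(ddof=1)
        assert z.loc["spironolactone/placebo", "y"] == pytest.approx(4.0 / sd_y)

    def test_one_sd_shift_moves_centered_z_by_one(self):
        mat, design = self._toy()
        sd = mat["x"].std(ddof=1)
        shifted = mat.copy()
        shifted.loc[["m3", "m4"], "x"] += sd
        z0 = zscore_profile(mat, design)
        z1 = zscore_profile(shifted, design)
        # pooled SD changes with the shift, so compare on the raw-scale effect
        d0 = z0.loc["spironolactone/placebo", "x"] * sd
        sd1 = shifted["x"].std(ddof=1)
        d1 = z1.loc["spironolactone/placebo", "x"] * sd1
        assert d1 - d0 == pytest.approx(sd)

    def test_zero_variance_column_rejected(self):
        mat, design = self._toy()
        mat["y"] = 5.0
        with pytest.raises(ValueError, match="y"):
            zscore_profile(mat, design)
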