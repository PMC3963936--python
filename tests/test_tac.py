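"""Decay arithmetic, TAC fitting and cumulated activity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from stunmird.emissions import TC99M_HALF_LIFE_H
from stunmird.tac import (
    FitError,
    TACFit,
    TACSample,
    cumulated_activity,
    decay,
    decay_correct,
    fit_tac,
    percent_id,
    tac_model,
)


class TestDecay:
    def test_three_days_of_decay_is_about_twelve_half_lives(self):
        assert 72.0 / TC99M_HALF_LIFE_H == pytest.approx(12.0, abs=0.05)
        assert round(decay(150.0, 72.0), 2) == 0.04

    def test_identity_and_one_half_life(self):
        assert decay(150.0, 0.0) == 150.0
        assert decay(150.0, TC99M_HALF_LIFE_H) == pytest.approx(75.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decay(150.0, 1.0, half_life=0.0)
        with pytest.raises(ValueError, match="decay_correct"):
            decay(150.0, -1.0)

    @given(
        activity=st.floats(1e-6, 1e4),
        elapsed=st.floats(0.0, 100.0),
        half_life=st.floats(0.1, 100.0),
    )
    def test_decay_then_correct_roundtrip(self, activity, elapsed, half_life):
        back = decay_correct(decay(activity, elapsed, half_life), elapsed, half_life)
        assert back == pytest.approx(activity, rel=1e-12)


class TestFit:
    def test_noiseless_exact_recovery(self):
        lam = 0.4
        a3 = 3.5 * np.exp(-lam * 2.0)
        a7 = 3.5 * np.exp(-lam * 6.0)
        fit = fit_tac([(1.0, 3.5), (3.0, a3), (7.0, a7)])
        assert fit.lambda_eff == pytest.approx(0.4, abs=1e-9)
        assert fit.peak_activity == pytest.approx(3.5, rel=1e-9)
        assert fit.peak_time == 1.0
        assert fit.uptake_slope == pytest.approx(3.5)

    def test_near_basal_by_eight_hours_when_washout_fast(self):
        """With lambda_eff >= 0.33/h the fitted curve at 8 h falls below 10%
        of the peak reached at 1 h."""
        for lam in (0.33, 0.4, 0.6):
            fit = TACFit(peak_time=1.0, peak_activity=3.5, lambda_eff=lam)
            assert tac_model(fit, 8.0) < 0.1 * fit.peak_activity

    def test_zero_post_peak_activity_rejected(self):
        with pytest.raises(FitError, match="> 0"):
            fit_tac([(1.0, 3.5), (3.0, 1.0), (7.0, 0.0)])

    def test_too_few_post_peak_samples_rejected(self):
        with pytest.raises(FitError, match="got 1"):
            fit_tac([(1.0, 3.5), (3.0, 1.0)])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(FitError, match="strictly increasing"):
            fit_tac([(1.0, 3.5), (1.0, 3.0), (7.0, 1.0)])

    def test_rising_washout_rejected(self):
        with pytest.raises(FitError, match="non-positive"):
            fit_tac([(1.0, 1.0), (3.0, 2.0), (7.0, 4.0)])

    def test_free_peak_mode_uses_argmax(self):
        lam = 0.3
        samples = [(0.5, 1.0), (2.0, 4.0), (4.0, 4.0 * np.exp(-2 * lam)), (8.0, 4.0 * np.exp(-6 * lam))]
        fit = fit_tac(samples, peak_time_mode="free")
        assert fit.peak_time == 2.0
        assert fit.lambda_eff == pytest.approx(lam, abs=1e-9)

    def test_fit_idempotence(self):
        """Refitting the fit's own predictions recovers the parameters."""
        fit = TACFit(peak_time=1.0, peak_activity=3.9, lambda_eff=0.27)
        times = np.array([1.0, 3.0, 7.0])
        refit = fit_tac(list(zip(times, tac_model(fit, times))))
        assert refit.lambda_eff == pytest.approx(fit.lambda_eff, rel=1e-12)
        assert refit.peak_activity == pytest.approx(fit.peak_activity, rel=1e-12)

    def test_slow_washout_warns(self):
        lam = 0.05  # slower than physical decay of Tc-99m
        with pytest.warns(UserWarning, match="physical decay"):
            fit_tac([(1.0, 3.5), (3.0, 3.5 * np.exp(-2 * lam)), (7.0, 3.5 * np.exp(-6 * lam))])

    def test_tac_sample_invariants(self):
        with pytest.raises(FitError):
            TACSample(time=1.0, activity=200.0, injected_activity=150.0)


class TestCumulated:
    @staticmethod
    def _quad_oracle(fit, t_end):
        up, _ = quad(lambda t: tac_model(fit, t), 0.0, fit.peak_time)
        down, _ = quad(lambda t: tac_model(fit, t), fit.peak_time, t_end)
        return (up + down) * 1e6 * 3600.0

    def test_closed_form_matches_quadrature(self):
        fit = TACFit(peak_time=1.0, peak_activity=1.0, lambda_eff=np.log(2) / 2.0)
        cum = cumulated_activity(fit, t_end=24.0)
        assert cum.value == pytest.approx(self._quad_oracle(fit, 24.0), rel=1e-6)

    def test_scales_linearly_with_peak_and_decreases_with_lambda(self):
        base = cumulated_activity(TACFit(1.0, 1.0, 0.3)).value
        assert cumulated_activity(TACFit(1.0, 2.0, 0.3)).value == pytest.approx(2 * base)
        assert cumulated_activity(TACFit(1.0, 1.0, 0.5)).value < base

    def test_fast_washout_limit_is_the_uptake_triangle(self):
        fit = TACFit(peak_time=1.0, peak_activity=2.0, lambda_eff=1e8)
        expected = 0.5 * 2.0 * 1.0 * 1e6 * 3600.0
        assert cumulated_activity(fit).value == pytest.approx(expected, rel=1e-6)

    def test_t_end_before_peak_rejected(self):
        with pytest.raises(ValueError, match="peak"):
            cumulated_activity(TACFit(2.0, 1.0, 0.3), t_end=1.0)


class TestPercentID:
    def test_paper_cohort_arithmetic(self):
        assert percent_id(3.945, 150.0) == pytest.approx(2.63)

    def test_zero_activity(self):
        assert percent_id(0.0, 150.0) == 0.0

    def test_decay_correction_factor(self):
        raw = percent_id(1.0, 150.0, elapsed=1.0, decay_correct_flag=False)
        corr = percent_id(1.0, 150.0, elapsed=1.0, decay_correct_flag=True)
        assert corr / raw == pytest.approx(2 ** (1.0 / TC99M_HALF_LIFE_H))

    def test_zero_injected_rejected(self):
        with pytest.raises(ValueError):
            percent_id(1.0, 0.0)
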