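"""Stunning quantification: percent change, threshold scan, recovery, qPCR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stunmird.io import stunning_records_from_frame
from stunmird.stunning import (
    StunningRecord,
    percent_change,
    qpcr_fold_changes,
    recovery_profile,
    relative_expression,
    threshold_scan,
)
from stunmird.synthetic import StunningConfig, synth_qpcr, synth_recovery, synth_stunning


class TestPercentChange:
    def test_forty_five_percent_stunning(self):
        assert percent_change(2.6, 1.43) == pytest.approx(-45.0)

    def test_identity_and_gain(self):
        assert percent_change(2.0, 2.0) == 0.0
        assert percent_change(2.0, 2.5) == pytest.approx(25.0)

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @given(a=st.floats(0.01, 100.0), b=st.floats(0.0, 100.0))
    def test_exact_identity(self, a, b):
        assert percent_change(a, b) == pytest.approx(100.0 * (b - a) / a, rel=1e-12)


def _records(doses, changes):
    return [
        StunningRecord(f"a{i:02d}", float(d), 2.6, 2.6 * (1 + c / 100.0))
        for i, (d, c) in enumerate(zip(doses, changes))
    ]


class TestThresholdScan:
    def test_recovers_a_simulated_22_gy_threshold(self):
        """Groups at -3.95% below and -17.5% above 22 Gy (SD 5, n=10/10):
        the split is significant essentially always and lands between the two
        doses bracketing 22 Gy in well over half of replicates (the smaller
        the groups, the noisier the exact split position)."""
        brackets = significants = 0
        for child in np.random.SeedSequence([20140324, 10]).spawn(20):
            rng = np.random.default_rng(child)
            d_lo = rng.uniform(5, 22, 10)
            d_hi = rng.uniform(22, 35, 10)
            doses = np.concatenate([d_lo, d_hi])
            tab = synth_stunning(StunningConfig(seed=int(rng.integers(2**31))), doses)
            res = threshold_scan(
                stunning_records_from_frame(tab), seed=int(rng.integers(2**31))
            )
            assert res.n_below + res.n_above == 20
            brackets += d_lo.max() < res.threshold < d_hi.min()
            significants += res.significant and res.mean_above < res.mean_below
        assert significants >= 18
        assert brackets >= 10

    def test_null_data_not_flagged(self):
        rng = np.random.default_rng(8)
        recs = _records(rng.uniform(5, 35, 30), rng.normal(-10, 5, 30))
        res = threshold_scan(recs, seed=8)
        assert not res.significant

    def test_uncorrected_mode_returns_smallest_significant_candidate(self):
        rng = np.random.default_rng(3)
        doses = np.sort(rng.uniform(5, 35, 24))
        changes = np.where(doses < 20.0, -3.95, -17.5) + rng.normal(0, 3, 24)
        res = threshold_scan(_records(doses, changes), adjust="none")
        below = res.candidates[res.candidates.p_naive < 0.05]
        assert len(below) > 0
        assert res.threshold == below.threshold_Gy.iloc[0]

    def test_all_records_one_side_of_every_candidate_rejected(self):
        # tied doses leave no split with 3 records on each side
        recs = _records([10, 10, 10, 10, 30, 30], [-4, -5, -3, -4, -18, -17])
        with pytest.raises(ValueError, match="on each side"):
            threshold_scan(recs)

    def test_identical_doses_rejected(self):
        recs = _records([20.0] * 10, np.linspace(-20, 0, 10))
        with pytest.raises(ValueError, match="identical"):
            threshold_scan(recs)

    def test_threshold_lies_between_observed_doses(self):
        rng = np.random.default_rng(5)
        doses = rng.uniform(5, 35, 20)
        tab = synth_stunning(StunningConfig(seed=5), doses)
        res = threshold_scan(stunning_records_from_frame(tab), seed=5)
        below = doses[doses < res.threshold]
        above = doses[doses > res.threshold]
        assert len(below) == res.n_below and len(above) == res.n_above


class TestRecovery:
    def test_synthetic_course_day1_2_impaired_day4_8_recovered(self):
        tab = synth_recovery(StunningConfig())
        prof = recovery_profile(stunning_records_from_frame(tab))
        assert prof.day(1).recovered is False and prof.day(1).p_vs_day0 < 0.05
        assert prof.day(2).recovered is False and prof.day(2).p_vs_day0 < 0.05
        assert prof.day(4).recovered is True
        assert prof.day(8).recovered is True
        assert prof.anova_p < 0.05

    def test_unchanged_uptake_recovers_every_day(self):
        recs = [
            StunningRecord(f"a{i}", 30.0, 2.5, 2.5, day=d)
            for i, d in enumerate([1, 1, 2, 2, 4, 4])
        ]
        prof = recovery_profile(recs)
        for day in prof.days:
            assert day.mean == pytest.approx(100.0)
            assert day.recovered is True

    def test_single_animal_day_has_no_sd_or_p(self):
        recs = [StunningRecord("a", 30.0, 2.5, 1.5, day=1)]
        prof = recovery_profile(recs)
        d = prof.day(1)
        assert d.sd is None and d.p_vs_day0 is None and d.recovered is None
        assert prof.anova_p is None

    def test_missing_day0_pairing_names_the_animal(self):
        with pytest.raises(ValueError, match="m42"):
            StunningRecord("m42", 30.0, float("nan"), 1.5, day=1)


class TestRelativeExpression:
    def test_anchor_points(self):
        assert relative_expression(20.0, 20.0) == 1.0
        assert relative_expression(21.0, 20.0) == 0.5

    def test_twelve_fold_ratio_between_samples(self):
        a = relative_expression(20.0, 20.0)
        b = relative_expression(20.0 + np.log2(12.0), 20.0)
        assert a / b == pytest.approx(12.0, rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(float("inf"), 20.0)

    @given(ct=st.floats(5.0, 35.0), delta=st.floats(0.01, 10.0))
    def test_unity_at_equal_ct_and_decreasing_in_target(self, ct, delta):
        assert relative_expression(ct, ct) == 1.0
        assert relative_expression(ct + delta, ct) < relative_expression(ct, ct)


class TestQpcrTable:
    def test_zero_noise_folds_exact(self):
        res = qpcr_fold_changes(synth_qpcr(sd=0.0))
        by = res.set_index("group")
        assert 1.0 / by.loc["20Gy", "fold_vs_control"] == pytest.approx(2.5, rel=1e-12)
        assert 1.0 / by.loc["30Gy", "fold_vs_control"] == pytest.approx(12.0, rel=1e-12)
        assert by.loc["5Gy", "fold_vs_control"] == pytest.approx(1.0, rel=1e-12)

    def test_noisy_downregulation_detected(self):
        res = qpcr_fold_changes(synth_qpcr(sd=0.5, seed=4))
        by = res.set_index("group")
        assert by.loc["30Gy", "p_vs_control"] < 0.05

    def test_missing_control_group_rejected(self):
        with pytest.raises(ValueError, match="control"):
            qpcr_fold_changes(synth_qpcr(sd=0.0), control_group="absent")
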