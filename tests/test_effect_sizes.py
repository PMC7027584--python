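"""Effect-size construction: SD recovery, arm combination, SMD, OR."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runinmeta import (PatientModel, SmdConfig, TrialSet, build_effects,
                       combine_arms, impute_sd, or_from_counts, sd_from_ci,
                       sd_from_p, sd_from_range, smd_change)
from runinmeta.effect_sizes import EffectSizeError
from runinmeta.synthetic_cohort import (SimConfig, degrade_reporting,
                                        simulate_trial_set)


class TestSdRecovery:
    @pytest.mark.parametrize("quantile,expected", [
        ("t", 5.0394), ("normal", 5.1021),
    ])
    def test_sd_from_p_matches_quantile_inversion(self, quantile, expected):
        cfg = SmdConfig(sd_recovery_quantile=quantile)
        assert sd_from_p(2.0, 50, 50, 0.05, cfg) == pytest.approx(
            expected, abs=1e-3)

    @pytest.mark.parametrize("quantile,expected", [
        ("t", 5.0394), ("normal", 5.1021),
    ])
    def test_sd_from_ci_matches_quantile_inversion(self, quantile, expected):
        cfg = SmdConfig(sd_recovery_quantile=quantile)
        assert sd_from_ci(-1.0, 3.0, 50, 50, cfg) == pytest.approx(
            expected, abs=1e-3)

    def test_sd_from_ci_location_invariant(self):
        assert sd_from_ci(-2.0, 2.0, 40, 60) == pytest.approx(
            sd_from_ci(5.0, 9.0, 40, 60))

    def test_p_and_ci_routes_agree_on_reconstructed_interval(self):
        # CI rebuilt from the same p and difference must give the same SD
        from scipy import stats
        diff, n1, n2, p = 1.7, 30, 45, 0.08
        tstar = stats.t.ppf(1 - p / 2, n1 + n2 - 2)
        se = diff / tstar
        q = stats.t.ppf(0.975, n1 + n2 - 2)
        sd_ci = sd_from_ci(diff - q * se, diff + q * se, n1, n2)
        assert sd_ci == pytest.approx(sd_from_p(diff, n1, n2, p), rel=1e-12)

    def test_growing_n_at_fixed_p_grows_sd(self):
        small = sd_from_p(2.0, 50, 50, 0.05)
        big = sd_from_p(2.0, 100, 100, 0.05)
        # SE fixed by p; SD scales with 1/sqrt(1/n1+1/n2) times a t-ratio
        from scipy import stats
        ratio = (math.sqrt(2) * stats.t.ppf(0.975, 98)
                 / stats.t.ppf(0.975, 198))
        assert big / small == pytest.approx(ratio, rel=1e-12)

    @pytest.mark.parametrize("width,expected", [(20.0, 5.0), (4.0, 1.0)])
    def test_sd_from_range_quarter_rule(self, width, expected):
        assert sd_from_range(width) == expected

    @pytest.mark.parametrize("call", [
        lambda: sd_from_p(0.0, 50, 50, 0.05),
        lambda: sd_from_p(2.0, 50, 50, 1.0),
        lambda: sd_from_ci(3.0, 3.0, 50, 50),
        lambda: sd_from_range(0.0),
        lambda: sd_from_range(-1.0),
    ])
    def test_degenerate_inputs_rejected(self, call):
        with pytest.raises(EffectSizeError):
            call()


class TestImputation:
    def _set_with_sds(self, synthetic_set, target_idx=0):
        ts = TrialSet(trials=list(synthetic_set.trials))
        return ts

    def test_imputes_mean_of_same_stratum_donors(self, synthetic_set):
        target = synthetic_set[0]
        donors = [t.drug.sd_change for t in synthetic_set
                  if t.trial_id != target.trial_id
                  and t.symptom == target.symptom
                  and t.instrument == target.instrument
                  and t.drug.sd_change is not None]
        assert donors  # generator ties instrument to symptom
        expected = sum(donors) / len(donors)
        got = impute_sd(synthetic_set, target.trial_id, "drug")
        assert got == pytest.approx(expected)

    def test_error_when_no_instrument_donors(self, synthetic_set):
        lonely = synthetic_set[0]
        object.__setattr__(lonely, "instrument", "UNIQUE-SCALE")
        try:
            with pytest.raises(EffectSizeError, match="cannot impute"):
                impute_sd(synthetic_set, lonely.trial_id, "drug")
        finally:
            object.__setattr__(lonely, "instrument",
                               {"diverse": "NPI", "psychosis": "BEHAVE-AD",
                                "agitation": "CMAI",
                                "aggression": "CMAI"}[lonely.symptom])


class TestCombineArms:
    def test_two_equal_n_arms(self):
        n, m, sd = combine_arms([(10, 1.0, 2.0), (10, 3.0, 2.0)])
        assert (n, m) == (20, 2.0)
        assert sd == pytest.approx(2.2005, abs=1e-4)

    def test_single_arm_identity(self):
        assert combine_arms([(12, 1.5, 3.0)]) == (12, 1.5, 3.0)

    def test_identical_arms_keep_moments(self):
        n, m, sd = combine_arms([(10, 2.0, 1.5), (10, 2.0, 1.5)])
        assert (n, m) == (20, 2.0)
        assert sd == pytest.approx(math.sqrt(9 * 2 * 1.5 ** 2 / 19))

    def test_empty_rejected(self):
        with pytest.raises(EffectSizeError):
            combine_arms([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.lists(st.integers(-5, 5), min_size=2, max_size=6),
                    min_size=1, max_size=4))
    def test_matches_patient_level_concatenation(self, samples):
        # combining arm summaries must equal moments of pooled raw data
        arms = []
        for sample in samples:
            if statistics.stdev(sample) == 0:
                return  # arm SD must be positive
            arms.append((len(sample), statistics.fmean(sample),
                         statistics.stdev(sample)))
        n, m, sd = combine_arms(arms)
        concat = [v for sample in samples for v in sample]
        assert n == len(concat)
        assert m == pytest.approx(statistics.fmean(concat), abs=1e-12)
        assert sd == pytest.approx(statistics.stdev(concat), rel=1e-10)


class TestSmd:
    def test_known_value(self):
        e = smd_change((100, -5.0, 10.0), (100, -3.0, 10.0))
        assert e.estimate == pytest.approx(-0.200)
        assert e.variance == pytest.approx(0.0201)
        assert e.se == pytest.approx(0.1418, abs=1e-4)

    def test_identical_arms_give_zero(self):
        e = smd_change((50, -2.0, 5.0), (50, -2.0, 5.0))
        assert e.estimate == 0.0

    def test_hedges_correction(self):
        e = smd_change((100, -5.0, 10.0), (100, -3.0, 10.0),
                       SmdConfig(hedges_correction=True))
        assert e.estimate == pytest.approx(-0.2 * (1 - 3 / 791))
        assert e.estimate == pytest.approx(-0.19924, abs=1e-5)
        assert "hedges_g" in e.corrections

    def test_hedges_shrinks_toward_zero_and_vanishes_with_n(self):
        for n in (10, 50, 500):
            d = smd_change((n, -4.0, 8.0), (n, -2.0, 8.0))
            g = smd_change((n, -4.0, 8.0), (n, -2.0, 8.0),
                           SmdConfig(hedges_correction=True))
            assert abs(g.estimate) < abs(d.estimate)
        big_d = smd_change((5000, -4.0, 8.0), (5000, -2.0, 8.0))
        big_g = smd_change((5000, -4.0, 8.0), (5000, -2.0, 8.0),
                           SmdConfig(hedges_correction=True))
        assert big_g.estimate == pytest.approx(big_d.estimate, rel=1e-3)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(EffectSizeError):
            smd_change((10, 1.0, 0.0), (10, 2.0, 0.0))

    @settings(derandomize=True, max_examples=100)
    @given(n1=st.integers(2, 200), n2=st.integers(2, 200),
           m1=st.floats(-10, 10), m2=st.floats(-10, 10),
           s1=st.floats(0.5, 10), s2=st.floats(0.5, 10))
    def test_antisymmetric_under_arm_swap(self, n1, n2, m1, m2, s1, s2):
        fwd = smd_change((n1, m1, s1), (n2, m2, s2))
        rev = smd_change((n2, m2, s2), (n1, m1, s1))
        assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-14)
        assert fwd.variance == pytest.approx(rev.variance, rel=1e-12)


class TestOddsRatio:
    def test_known_value(self):
        e = or_from_counts(10, 100, 5, 100)
        assert math.exp(e.estimate) == pytest.approx(950 / 450)
        assert e.se == pytest.approx(0.5671, abs=1e-4)
        assert e.corrections == []

    def test_symmetric_counts_give_unit_or(self):
        e = or_from_counts(10, 100, 10, 100)
        assert e.estimate == 0.0

    def test_single_zero_cell_continuity(self):
        e = or_from_counts(0, 100, 5, 100)
        assert math.exp(e.estimate) == pytest.approx(
            (0.5 * 95.5) / (100.5 * 5.5))
        assert e.corrections == ["continuity_0.5"]

    def test_double_zero_marker(self):
        assert or_from_counts(0, 50, 0, 50) is None

    def test_doubling_counts_preserves_point_estimate(self):
        a = or_from_counts(8, 100, 4, 90)
        b = or_from_counts(16, 200, 8, 180)
        assert a.estimate == pytest.approx(b.estimate)

    def test_bad_inputs_rejected(self):
        with pytest.raises(EffectSizeError):
            or_from_counts(1, 0, 1, 10)
        with pytest.raises(EffectSizeError):
            or_from_counts(11, 10, 1, 10)

    @settings(derandomize=True, max_examples=100)
    @given(e1=st.integers(0, 50), e2=st.integers(0, 50),
           n1=st.integers(50, 200), n2=st.integers(50, 200))
    def test_antisymmetric_under_arm_swap(self, e1, e2, n1, n2):
        fwd = or_from_counts(e1, n1, e2, n2)
        rev = or_from_counts(e2, n2, e1, n1)
        if fwd is None:
            assert rev is None
            return
        assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-12)
        assert fwd.variance == pytest.approx(rev.variance, rel=1e-12)


class TestBuildEffects:
    def test_complete_set_all_reported(self, synthetic_set):
        eff = build_effects(synthetic_set, "efficacy")
        assert len(eff) == len(synthetic_set)
        assert all(e.sd_source == "reported" for e in eff)
        assert eff.skipped == []

    def test_sd_source_follows_reporting_precedence(self, synthetic_set):
        degraded = degrade_reporting(
            synthetic_set, {"to_p": 0.2, "to_ci": 0.2, "to_range": 0.2,
                            "remove": 0.2}, seed=5)
        eff = build_effects(degraded, "efficacy")
        sources = {e.sd_source for e in eff}
        assert {"reported", "from_p", "from_ci", "from_range",
                "imputed"} <= sources

    def test_missing_outcome_counted_as_skipped(self, table1):
        eff = build_effects(table1, "efficacy")
        assert len(eff) == 0
        assert len(eff.skipped) == 35
        assert all(reason == "no_change_data" for _, reason in eff.skipped)

    def test_double_zero_trials_logged(self, small_set):
        muted = simulate_trial_set(SimConfig(
            n_trials=4, patients_per_trial=60, seed=2,
            patient_model=PatientModel(p_death_plc=0.0, or_death=1.0)))
        eff = build_effects(muted, "mortality")
        assert len(eff) + len(eff.skipped) == 4
        assert any(r == "both_arms_zero_events" for _, r in eff.skipped)

    def test_unknown_outcome_rejected(self, small_set):
        with pytest.raises(ValueError, match="efficacy"):
            build_effects(small_set, "nonsense")
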