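"""Dichotomization, propensity/IPTW, pseudo-population, ATE."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemolift.synthetic import (
    DEFAULT_ADJUSTMENT_SET,
    _standardize,
    default_spec,
    generate_cohort,
)
from hemolift.treatment import (
    DichotomizationRule,
    IPTWWeights,
    build_and_sample_pseudo_population,
    dichotomize,
    estimate_ate,
    fit_propensity,
    hajek_ate,
    iptw_weights,
    replication_counts,
    standardized_mean_differences,
)


def _arms(cohort, rule=None):
    rule = rule or DichotomizationRule()
    return dichotomize(cohort.tifb, cohort.ne, rule)


class TestDichotomize:
    @pytest.mark.parametrize(
        "tifb, ne, expected",
        [
            # published arm medians fall on the expected sides of the line
            (5.19, 0.00, 1),   # threshold 0.0638
            (1.74, 0.04, 0),   # threshold -0.0052
            (2.0, 0.0, 0),     # ne exactly on the line -> control
        ],
    )
    def test_examples(self, tifb, ne, expected):
        rule = DichotomizationRule(slope=0.02, offset=-0.04)
        assert dichotomize(tifb, ne, rule) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.array([np.nan]), np.array([0.0]), DichotomizationRule())

    @given(
        tifb=st.floats(0, 20),
        ne=st.floats(0, 0.5),
        bump=st.floats(0, 0.3),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_ne_and_offset(self, tifb, ne, bump):
        rule = DichotomizationRule()
        # raising ne never moves a patient into the treatment arm
        assert dichotomize(tifb, ne + bump, rule) <= dichotomize(tifb, ne, rule)
        # raising the offset never shrinks the treatment arm
        wider = rule.with_offset(rule.offset + bump)
        assert dichotomize(tifb, ne, wider) >= dichotomize(tifb, ne, rule)

    def test_rule_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            DichotomizationRule(offset_grid=(0.1, 0.0, -0.04))
        with pytest.raises(ValueError, match="contain"):
            DichotomizationRule(offset=-0.05)


class TestPropensity:
    def test_no_confounding_gives_flat_scores(self):
        spec = dataclasses.replace(
            default_spec(n_patients=20_000, seed=0), confounding_coefs={}
        )
        cohort = generate_cohort(spec)
        arms = _arms(cohort)
        result = fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET)
        assert np.abs(result.scores - arms.mean()).max() < 0.06

    @pytest.mark.parametrize("seed", range(20))
    def test_coefficient_recovery_within_3se(self, seed):
        spec = dataclasses.replace(default_spec(seed=seed), n_patients=5000)
        cohort = generate_cohort(spec)
        arms = _arms(cohort)
        # fit on standardized confounders so truth equals the generator coefficients
        z = _standardize(cohort.df, spec)
        zc = cohort.__class__(
            cohort.df.assign(**{f"z_{k}": z[k] for k in DEFAULT_ADJUSTMENT_SET}),
            [f"z_{k}" for k in DEFAULT_ADJUSTMENT_SET],
        )
        res = fit_propensity(zc, arms, zc.covariate_names)
        for name in DEFAULT_ADJUSTMENT_SET:
            truth = spec.confounding_coefs[name]
            est, se = res.params[f"z_{name}"], res.bse[f"z_{name}"]
            assert abs(est - truth) < 3 * se

    def test_unknown_adjustment_name_is_reported(self, study_cohort):
        arms = _arms(study_cohort)
        with pytest.raises(KeyError, match="nope"):
            fit_propensity(study_cohort, arms, ["age", "nope"])

    def test_single_arm_rejected(self, study_cohort):
        with pytest.raises(ValueError, match="both arms"):
            fit_propensity(study_cohort, np.ones(len(study_cohort), int), ["age"])

    def test_scores_clipped_and_overlap_reported(self, study_cohort):
        arms = _arms(study_cohort)
        res = fit_propensity(study_cohort, arms, DEFAULT_ADJUSTMENT_SET,
                             clip_epsilon=0.05)
        assert res.scores.min() >= 0.05 and res.scores.max() <= 0.95
        lo, hi = res.overlap_summary["shared_support"]
        assert lo < hi


class TestWeights:
    def test_closed_forms(self):
        prop = type("P", (), {"scores": np.array([0.5, 0.25, 0.25])})
        w = iptw_weights(prop, np.array([1, 1, 0]))
        np.testing.assert_allclose(w.weights, [2.0, 4.0, 4.0 / 3.0])

    def test_weights_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            IPTWWeights(np.array([0.5]))

    def test_arm_weight_sums_estimate_cohort_size(self, large_confounded_cohort):
        cohort = large_confounded_cohort
        arms = _arms(cohort)
        w = iptw_weights(fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET), arms)
        n = len(cohort)
        assert w.weights[arms == 1].sum() == pytest.approx(n, rel=0.1)
        assert w.weights[arms == 0].sum() == pytest.approx(n, rel=0.1)

    def test_weighting_balances_confounders(self, large_confounded_cohort):
        cohort = large_confounded_cohort
        arms = _arms(cohort)
        X = cohort.features(DEFAULT_ADJUSTMENT_SET)
        before = standardized_mean_differences(X, arms)
        w = iptw_weights(fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET), arms)
        after = standardized_mean_differences(X, arms, w.weights)
        assert before.abs().max() > 0.1          # genuinely confounded
        assert after.abs().max() < 0.1           # balanced after weighting


class TestPseudoPopulation:
    def test_rounding_rule_half_away_from_zero(self):
        counts = replication_counts(np.array([1.0, 1.23456, 2.00005, 1.00005]), 10_000)
        np.testing.assert_array_equal(counts, [10_000, 12_346, 20_001, 10_001])

    def test_uniform_limit(self, study_cohort):
        arms = _arms(study_cohort)
        w = IPTWWeights(np.ones(len(study_cohort)))
        pp = build_and_sample_pseudo_population(
            study_cohort, arms, w, n_per_arm=2000, seed=0
        )
        assert len(pp) == 4000
        assert (pp.arm == 1).sum() == 2000 and (pp.arm == 0).sum() == 2000
        # every sampled record traces to a source patient of the same arm
        assert (arms[pp.indices] == pp.arm).all()
        # uniform weights -> roughly uniform resampling frequencies
        counts = np.bincount(pp.indices[pp.arm == 1], minlength=len(study_cohort))
        expected = 2000 / arms.sum()
        assert counts[arms == 1].mean() == pytest.approx(expected, rel=0.05)

    def test_deterministic_given_seed(self, study_cohort):
        arms = _arms(study_cohort)
        w = IPTWWeights(np.ones(len(study_cohort)))
        a = build_and_sample_pseudo_population(study_cohort, arms, w, 500, seed=9)
        b = build_and_sample_pseudo_population(study_cohort, arms, w, 500, seed=9)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_sampled_pseudo_population_is_balanced(self, large_confounded_cohort):
        cohort = large_confounded_cohort
        arms = _arms(cohort)
        w = iptw_weights(fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET), arms)
        pp = build_and_sample_pseudo_population(cohort, arms, w, n_per_arm=5000, seed=1)
        smd = standardized_mean_differences(
            pp.features(DEFAULT_ADJUSTMENT_SET), pp.arm
        )
        assert smd.abs().max() < 0.1

    def test_contracts(self, study_cohort):
        arms = _arms(study_cohort)
        w = IPTWWeights(np.ones(len(study_cohort)))
        with pytest.raises(ValueError, match="n_per_arm"):
            build_and_sample_pseudo_population(study_cohort, arms, w, 0)
        with pytest.raises(ValueError, match="multiplier"):
            build_and_sample_pseudo_population(study_cohort, arms, w, 10, multiplier=0)


class TestAte:
    def test_null_effect_without_confounding(self):
        spec = dataclasses.replace(
            default_spec(n_patients=4000, seed=1, effect="null"),
            confounding_coefs={},
        )
        cohort = generate_cohort(spec)
        arms = _arms(cohort)
        w = iptw_weights(fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET), arms)
        ate, lo, hi = estimate_ate(cohort, arms, w, n_boot=100, seed=0)
        assert abs(ate) < 0.05
        assert lo <= ate <= hi

    def test_degenerate_all_beneficial(self, study_cohort):
        cohort = study_cohort
        arms = _arms(cohort)
        df = cohort.df.assign(outcome_beneficial=1)
        ones = cohort.__class__(df, cohort.covariate_names)
        w = IPTWWeights(np.ones(len(cohort)))
        assert hajek_ate(ones.outcomes, arms, w) == 0.0

    def test_iptw_corrects_confounding_bias(self, large_confounded_cohort):
        cohort = large_confounded_cohort
        arms = _arms(cohort)
        truth = cohort.true_uplift.mean()
        naive = cohort.outcomes[arms == 1].mean() - cohort.outcomes[arms == 0].mean()
        w = iptw_weights(fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET), arms)
        adjusted = hajek_ate(cohort.outcomes, arms, w)
        assert naive - truth > 0.02              # confounding inflates the contrast
        assert abs(adjusted - truth) < abs(naive - truth)
        assert abs(adjusted - truth) < 0.03

    def test_unadjusted_and_iptw_agree_without_confounding(self):
        spec = dataclasses.replace(
            default_spec(n_patients=5000, seed=4), confounding_coefs={}
        )
        cohort = generate_cohort(spec)
        arms = _arms(cohort)
        naive = cohort.outcomes[arms == 1].mean() - cohort.outcomes[arms == 0].mean()
        w = iptw_weights(fit_propensity(cohort, arms, DEFAULT_ADJUSTMENT_SET), arms)
        assert hajek_ate(cohort.outcomes, arms, w) == pytest.approx(naive, abs=0.02)

    def test_n_boot_contract(self, study_cohort):
        arms = _arms(study_cohort)
        w = IPTWWeights(np.ones(len(study_cohort)))
        with pytest.raises(ValueError, match="n_boot"):
            estimate_ate(study_cohort, arms, w, n_boot=1)
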