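"""Synthetic cohort generator: calibration, determinism and noise contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronoprof import GeneratorConfig, generate_cohort
from chronoprof.generate import (CONTACT_PROB, PROFILE_WEIGHTS, ConfigError,
                                 inject_missingness, median_zero_noise,
                                 sample_contacts, sample_profiles)
from chronoprof.schema import SLOT_NAMES


class TestProfiles:
    def test_degenerate_weights_give_constant_labels(self, rng):
        assert (sample_profiles(500, (1, 0, 0, 0), rng) == 1).all()

    def test_invalid_weights_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_profiles(10, (0.5, 0.2, 0.2, 0.2), rng)

    def test_profile_shares_converge_to_weights(self, rng):
        n = 100_000
        lab = sample_profiles(n, PROFILE_WEIGHTS, rng)
        p3 = 55 / 173
        se = np.sqrt(p3 * (1 - p3) / n)
        assert abs((lab == 3).mean() - p3) < 3 * se

    def test_goodness_of_fit_calibrated_across_seeds(self):
        w = np.array([float(x) for x in PROFILE_WEIGHTS])
        ok = 0
        for seed in range(20):
            lab = sample_profiles(5000, PROFILE_WEIGHTS,
                                  np.random.default_rng(seed))
            obs = np.bincount(lab, minlength=5)[1:]
            _, p = stats.chisquare(obs, w * 5000)
            ok += p > 0.01
        assert ok >= 18


class TestContacts:
    def test_deterministic_slots_are_exact(self, rng):
        lab = np.full(300, 2)           # profile 2: every snack certain
        flags = sample_contacts(lab, CONTACT_PROB, rng)
        assert (flags["morning_snack"] == 1).all()
        assert (flags["evening_snack"] == 1).all()
        lab1 = np.full(300, 1)          # profile 1: no nibbling ever
        flags1 = sample_contacts(lab1, CONTACT_PROB, rng)
        for slot in ("morning_nibbling", "afternoon_nibbling",
                     "evening_nibbling", "night_nibbling"):
            assert (flags1[slot] == 0).all()

    def test_profile3_afternoon_nibbling_prevalence(self, rng):
        n = 50_000
        flags = sample_contacts(np.full(n, 3), CONTACT_PROB, rng)
        p = 22 / 55
        assert abs(flags["afternoon_nibbling"].mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_overall_breakfast_prevalence_matches_mixture_arithmetic(self):
        # brute-force mixture sum as the oracle
        expected = sum(float(w) * float(p) for w, p in
                       zip(PROFILE_WEIGHTS, CONTACT_PROB["breakfast"]))
        cohort, _ = generate_cohort(GeneratorConfig(n=100_000, seed=11))
        assert abs(cohort["breakfast"].mean() - expected) < 0.004
        assert abs(expected - 154 / 173) < 1e-12


class TestCovariatesAndOutcomes:
    def test_bmi_support_and_median(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=30_000, seed=5))
        bmi = cohort["BMI"]
        assert bmi.min() >= 32.9 and bmi.max() <= 80.3
        assert abs(bmi.median() - 43.0) < 0.5

    def test_age_support_and_median(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=30_000, seed=5))
        assert cohort["age"].between(17, 71).all()
        assert abs(cohort["age"].median() - 46) < 1.0

    def test_median_zero_noise_contract(self, rng):
        for scale, sigma in [(0.3, 0.7), (15.0, 0.6), (2.0, 0.8)]:
            draws = median_zero_noise(1_000_000, scale, sigma, rng)
            assert abs(np.median(draws)) < 0.01 * scale
            assert stats.skew(draws) > 0          # right-skewed by design

    def test_zero_coefficient_logistic_outcome_has_half_prevalence(self, rng):
        cfg = GeneratorConfig(n=20_000, seed=2)
        cfg.outcome_params = dict(cfg.outcome_params)
        cfg.outcome_params["hypertension"] = {
            "family": "logistic", "intercept": 0.0, "coef": {}}
        cohort, _ = generate_cohort(cfg)
        assert abs(cohort["hypertension"].mean() - 0.5) < 0.02

    def test_unknown_covariate_in_formula_rejected(self):
        cfg = GeneratorConfig(n=10)
        cfg.outcome_params = dict(cfg.outcome_params)
        cfg.outcome_params["HDL"] = {"family": "median", "intercept": 0,
                                     "coef": {"nope": 1.0},
                                     "noise_scale": 1, "noise_sigma": 0.5}
        with pytest.raises(ConfigError, match="nope"):
            generate_cohort(cfg)

    def test_homa_missing_under_insulin_treatment(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=30_000, seed=5))
        treated = cohort["insulin_treated"] == 1
        assert treated.any()
        assert cohort.loc[treated, "HOMA"].isna().all()


class TestMissingness:
    def test_zero_rates_leave_table_complete(self, small_cohort, rng):
        cohort, _ = small_cohort
        complete = cohort.fillna(0.0)
        out = inject_missingness(complete, {}, rng)
        assert not out.isna().any().any()

    def test_marginal_rate_hits_target(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=100_000, seed=9))
        rate = cohort["HDL"].isna().mean()
        assert abs(rate - 0.15) < 3 * np.sqrt(0.15 * 0.85 / len(cohort))

    def test_rate_for_unknown_column_rejected(self, small_cohort, rng):
        cohort, _ = small_cohort
        with pytest.raises(ConfigError):
            inject_missingness(cohort, {"no_such": 0.1}, rng)

    def test_mechanism_is_mar_given_covariates(self):
        # mask ⟂ hidden value | (age, gender): logistic coefficient on the
        # hidden value should be ~0 after adjustment
        import statsmodels.api as sm
        cohort, truth = generate_cohort(GeneratorConfig(n=50_000, seed=13))
        mask = cohort["HDL"].isna().astype(float).to_numpy()
        hidden = truth["hidden_HDL"].to_numpy()
        X = np.column_stack([np.ones_like(hidden), hidden,
                             cohort["age"].to_numpy(),
                             (cohort["gender"] == "M").to_numpy(float)])
        fit = sm.Logit(mask, X).fit(disp=0)
        assert abs(fit.params[1]) < 3 * fit.bse[1]


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        from chronoprof import write_cohort_csv
        a, _ = generate_cohort(GeneratorConfig(n=173, seed=4))
        b, _ = generate_cohort(GeneratorConfig(n=173, seed=4))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(a, pa)
        write_cohort_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_schema_contract_at_n173(self):
        cohort, truth = generate_cohort(GeneratorConfig(n=173, seed=1))
        assert len(cohort) == 173
        assert all(s in cohort.columns for s in SLOT_NAMES)
        assert "true_profile" in truth.columns
        assert "profile_label" not in cohort.columns   # labels stay hidden
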