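"""Varying-coefficient along-tract statistics: estimation, tests, FDR."""

import numpy as np
import pandas as pd
import pytest

import tractokit as tk
from tractokit.core import StructuralError
from tractokit.formats import read_profile_csv, write_profile_csv
from tractokit.stats import (VCModelSpec, export_stats_csv, fit_vcm,
                             global_test, local_test_fdr, run_stats)
from tractokit.synthetic import CohortSpec, simulate_profile_cohort


def bh_stepup(pvals, q):
    """Brute-force Benjamini-Hochberg step-up oracle."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, n + 1)) / n
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(n, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFit:
    def test_zero_beta_zero_noise_gives_zero_coefficients(self):
        spec = CohortSpec(n_subjects=8, noise_sd=0.0, seed=3)
        prof, cov, _ = simulate_profile_cohort(spec)
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        k = fit.covariate_names.index("age")
        assert np.abs(fit.betas[k][fit.valid]).max() < 1e-10

    def test_known_effect_recovered_at_n40(self):
        curve = lambda s: 0.05 * np.exp(-((s - 5.0) / 6.0) ** 2)
        spec = CohortSpec(n_subjects=40, noise_sd=0.01,
                          beta_functions={"age": curve}, seed=11)
        prof, cov, betas = simulate_profile_cohort(spec)
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        k = fit.covariate_names.index("age")
        err = np.abs(fit.betas[k] - betas["age"]).max()
        assert err < 0.1 * betas["age"].max()

    def test_duplication_invariance(self):
        spec = CohortSpec(n_subjects=10, noise_sd=0.02, seed=5)
        prof, cov, _ = simulate_profile_cohort(spec)
        fit1 = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        dup = prof.copy()
        cov2 = pd.concat([cov, cov.rename(index=lambda s: s + "b")])
        for c in cov.index:
            dup[c + "b"] = prof[c]
        fit2 = fit_vcm(dup, cov2, VCModelSpec(covariates=["age"]))
        assert np.allclose(fit1.betas, fit2.betas, atol=1e-10,
                           equal_nan=True)

    def test_rank_deficient_design_names_columns(self):
        spec = CohortSpec(n_subjects=8, noise_sd=0.01, seed=1)
        prof, cov, _ = simulate_profile_cohort(spec)
        cov = cov.copy()
        cov["age2"] = cov["age"]
        with pytest.raises(StructuralError, match="age2"):
            fit_vcm(prof, cov, VCModelSpec(covariates=["age", "age2"]))

    def test_missing_bins_dropped_and_flagged(self):
        spec = CohortSpec(n_subjects=10, noise_sd=0.01, seed=2)
        prof, cov, _ = simulate_profile_cohort(spec)
        prof = prof.copy()
        prof.iloc[3, 1:] = np.nan            # whole bin missing
        prof.iloc[10, 1] = np.nan            # one subject missing
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        assert not fit.valid[3]
        assert fit.valid[10]

    def test_fpca_explains_variance(self):
        spec = CohortSpec(n_subjects=20, noise_sd=0.05, seed=8)
        prof, cov, _ = simulate_profile_cohort(spec)
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        assert fit.fpca_var_explained >= 0.95
        assert fit.fpca_components.shape[1] == fit.valid.sum()


class TestGlobalTest:
    def test_strong_effect_reaches_p_floor(self):
        curve = lambda s: 0.05 * np.exp(-((s - 2.0) / 8.0) ** 2)
        spec = CohortSpec(n_subjects=30, noise_sd=0.01,
                          beta_functions={"age": curve}, seed=4)
        prof, cov, _ = simulate_profile_cohort(spec)
        ms = VCModelSpec(covariates=["age"], n_resamples=199, seed=0)
        fit = fit_vcm(prof, cov, ms)
        p = global_test(fit, "age")
        assert p == pytest.approx(1.0 / 200.0)

    def test_seeded_determinism(self):
        spec = CohortSpec(n_subjects=12, noise_sd=0.03, seed=6)
        prof, cov, _ = simulate_profile_cohort(spec)
        ms = VCModelSpec(covariates=["age"], n_resamples=100, seed=3)
        fit = fit_vcm(prof, cov, ms)
        assert global_test(fit, "age") == global_test(fit, "age")

    def test_type_one_error_near_nominal(self):
        rejections = 0
        n_sim = 100
        for i in range(n_sim):
            spec = CohortSpec(n_subjects=15, noise_sd=0.03, seed=4000 + i)
            prof, cov, _ = simulate_profile_cohort(spec)
            ms = VCModelSpec(covariates=["age"], n_resamples=200, seed=i)
            fit = fit_vcm(prof, cov, ms)
            if global_test(fit, "age") < 0.05:
                rejections += 1
        assert 0.0 <= rejections / n_sim <= 0.12

    def test_unknown_covariate_rejected(self):
        spec = CohortSpec(n_subjects=8, noise_sd=0.02, seed=9)
        prof, cov, _ = simulate_profile_cohort(spec)
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        with pytest.raises(StructuralError, match="sex"):
            global_test(fit, "sex")


class TestLocalFdr:
    def test_bh_agrees_with_brute_force(self):
        rng = np.random.default_rng(0)
        from statsmodels.stats.multitest import multipletests
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            p = rng.uniform(size=n)
            q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
            ours, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
            assert np.array_equal(ours, bh_stepup(p, q))

    def test_hand_computed_bh_example(self):
        assert np.array_equal(bh_stepup([0.001, 0.01, 0.02, 0.8], 0.05),
                              [True, True, True, False])

    def test_all_p_one_empty_mask(self):
        spec = CohortSpec(n_subjects=10, noise_sd=0.0, seed=2)
        prof, cov, _ = simulate_profile_cohort(spec)
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        res = local_test_fdr(fit, "age")
        # zero effect, zero noise: betas 0, p-values 1 -> nothing significant
        assert res.significant.sum() == 0

    def test_corrected_p_not_below_raw(self):
        curve = lambda s: 0.02 * np.exp(-((s - 5.0) / 6.0) ** 2)
        spec = CohortSpec(n_subjects=20, noise_sd=0.02,
                          beta_functions={"age": curve}, seed=7)
        prof, cov, _ = simulate_profile_cohort(spec)
        fit = fit_vcm(prof, cov, VCModelSpec(covariates=["age"]))
        res = local_test_fdr(fit, "age")
        ok = ~np.isnan(res.p_raw)
        assert np.all(res.p_fdr[ok] >= res.p_raw[ok] - 1e-12)


class TestExport:
    def test_schema_and_round_trip(self, tmp_path):
        curve = lambda s: 0.02 * np.ones_like(s)
        spec = CohortSpec(n_subjects=12, noise_sd=0.02,
                          beta_functions={"age": curve}, seed=10)
        prof, cov, _ = simulate_profile_cohort(spec)
        ms = VCModelSpec(covariates=["age"], n_resamples=50, seed=1)
        results = run_stats(prof, cov, ms)
        df = export_stats_csv(results)
        assert list(df.columns) == ["arclength", "beta_age", "p_age",
                                    "pFDR_age"]
        path = tmp_path / "stats.csv"
        write_profile_csv(df, path)
        back = read_profile_csv(path)
        assert np.allclose(back["arclength"], df["arclength"])
        assert np.allclose(back["beta_age"], df["beta_age"], equal_nan=True)
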