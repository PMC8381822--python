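"""Phenotype correction, genotype-mean likelihood machinery, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mnqtl.qtl import (
    GenotypeVector,
    correct_phenotype,
    fit_snp,
    permutation_threshold,
    scan,
    scan_with_threshold,
    seasonal_difference,
)


def _balanced_genotypes(n_per_class):
    return np.repeat([1, 0, -1], n_per_class).astype(float)


class TestCorrectPhenotype:
    def test_no_covariates_centers(self, rng):
        y = pd.Series(rng.normal(5, 1, 50))
        resid = correct_phenotype(y)
        assert resid.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(resid, y - y.mean())

    def test_residuals_orthogonal_to_covariate(self, rng):
        age = rng.uniform(20, 70, 80)
        y = pd.Series(2.0 * age + rng.normal(0, 1, 80))
        resid = correct_phenotype(y, pd.DataFrame({"age": age}))
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10

    def test_group_effect_removed(self, rng):
        sex = rng.integers(0, 2, 200)
        y = pd.Series(3.0 * sex + rng.normal(0, 1, 200))
        resid = correct_phenotype(y, pd.DataFrame({"sex": sex}))
        assert abs(resid[sex == 1].mean() - resid[sex == 0].mean()) < 1e-8

    def test_collinear_covariates_named(self, rng):
        age = rng.uniform(20, 70, 40)
        cov = pd.DataFrame({"age": age, "age_months": age * 12})
        with pytest.raises(ValueError, match="age_months"):
            correct_phenotype(pd.Series(rng.normal(0, 1, 40)), cov)

    def test_gls_whitening_with_known_covariance(self, rng):
        # with an identity relatedness matrix GLS must equal OLS
        age = rng.uniform(20, 70, 30)
        y = pd.Series(age + rng.normal(0, 1, 30))
        cov = pd.DataFrame({"age": age})
        ols = correct_phenotype(y, cov)
        gls = correct_phenotype(y, cov, kinship=np.eye(30))
        np.testing.assert_allclose(ols, gls, atol=1e-10)


class TestFitSnp:
    def test_constant_phenotype_gives_zero_lrt(self):
        g = _balanced_genotypes(4)
        fit = fit_snp(np.full(12, 3.0), g)
        assert fit.lrt == 0.0 and fit.degenerate

    def test_zero_within_class_variance_floored_and_flagged(self):
        g = np.array([1.0, 1, 1, -1, -1, -1])
        with pytest.warns(UserWarning, match="zero within-class variance"):
            fit = fit_snp(np.array([0.0, 0, 0, 1, 1, 1]), g)
        assert fit.degenerate and fit.lrt > 0

    def test_lrt_matches_log_density_oracle(self, rng):
        g = _balanced_genotypes(20)
        y = rng.normal(0, 1, 60) + 0.3 * g
        fit = fit_snp(y, g)
        # independent oracle: sum normal log-densities under both models
        ll1 = 0.0
        for c in (1, 0, -1):
            yc = y[g == c]
            ll1 += stats.norm.logpdf(yc, yc.mean() if False else fit.means[c],
                                     np.sqrt(fit.sigma2)).sum()
        ll0 = stats.norm.logpdf(y, y.mean(), np.sqrt(fit.sigma2_null)).sum()
        assert fit.lrt == pytest.approx(2 * (ll1 - ll0), abs=1e-10)
        assert fit.loglik_alt == pytest.approx(ll1, abs=1e-10)

    def test_class_means_are_mles(self, rng):
        g = _balanced_genotypes(10)
        y = rng.normal(0, 1, 30)
        fit = fit_snp(y, g)
        for c in (1, 0, -1):
            assert fit.means[c] == pytest.approx(y[g == c].mean())

    def test_small_class_dropped_with_warning(self, rng):
        g = np.array([1.0] * 10 + [0.0] * 10 + [-1.0])
        y = rng.normal(0, 1, 21)
        with pytest.warns(UserWarning, match="dropped genotype classes"):
            fit = fit_snp(y, g)
        assert fit.n == 20 and fit.n_classes == 2

    def test_affine_invariance_of_lrt(self, rng):
        g = _balanced_genotypes(15)
        y = rng.normal(0, 1, 45) + 0.4 * g
        base = fit_snp(y, g).lrt
        shifted = fit_snp(7.5 * y - 300.0, g).lrt
        assert shifted == pytest.approx(base, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_snp(np.arange(6.0), np.ones(6))

    def test_missing_genotypes_dropped_per_snp(self, rng):
        g = _balanced_genotypes(10)
        g[0] = np.nan
        y = rng.normal(0, 1, 30)
        fit = fit_snp(y, g)
        assert fit.n == 29


class TestScan:
    def test_vectorized_scan_matches_per_snp_fit(self, rng):
        n, p = 60, 15
        G = pd.DataFrame(rng.integers(-1, 2, (n, p)).astype(float),
                         columns=[f"s{j}" for j in range(p)])
        G.iloc[0, 0] = np.nan
        y = rng.normal(0, 1, n)
        table = scan(y, G)
        for j, snp in enumerate(G.columns):
            expect = fit_snp(y, G[snp].to_numpy())
            assert table.loc[j, "lrt"] == pytest.approx(expect.lrt, abs=1e-9)

    def test_null_lrt_follows_chi2_two_df(self, rng):
        # 3 balanced classes, null phenotype: LRT is asymptotically chi2(2)
        n = 300
        g = pd.DataFrame({"s": _balanced_genotypes(n // 3)})
        lrts = [scan(rng.normal(0, 1, n), g)["lrt"].iloc[0] for _ in range(400)]
        # compare upper quantile against the chi2(2) value 5.99
        q95 = np.quantile(lrts, 0.95)
        assert 5.0 < q95 < 7.0


class TestPermutationThreshold:
    @pytest.fixture()
    def data(self, rng):
        G = pd.DataFrame(rng.integers(-1, 2, (80, 12)).astype(float))
        y = rng.normal(0, 1, 80)
        return y, G

    def test_alpha_one_gives_minimum_of_maxima(self, data):
        y, G = data
        thr = permutation_threshold(y, G, n_perm=100, alpha=1.0, seed=3)
        # alpha = 1 keeps the 0-quantile: the smallest max-LRT
        thr05 = permutation_threshold(y, G, n_perm=100, alpha=0.05, seed=3)
        assert thr <= thr05

    def test_threshold_monotone_in_alpha(self, data):
        y, G = data
        thrs = [permutation_threshold(y, G, n_perm=200, alpha=a, seed=7)
                for a in (0.01, 0.05, 0.10, 0.50)]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_bit_reproducible_under_seed(self, data):
        y, G = data
        a = permutation_threshold(y, G, n_perm=150, alpha=0.05, seed=11)
        b = permutation_threshold(y, G, n_perm=150, alpha=0.05, seed=11)
        assert a == b

    def test_family_wise_error_calibrated(self, rng):
        # null cohorts: the chance that any SNP beats the 5% genome-wide
        # threshold should be ~5%
        n, p, reps = 100, 200, 150
        hits = 0
        for rep in range(reps):
            freq = rng.uniform(0.2, 0.5, p)
            G = pd.DataFrame(
                ((rng.random((n, p)) < freq).astype(int)
                 + (rng.random((n, p)) < freq).astype(int) - 1).astype(float))
            y = rng.normal(0, 1, n)
            thr = permutation_threshold(y, G, n_perm=150, alpha=0.05, seed=rep)
            hits += scan(y, G)["lrt"].max() > thr
        rate = hits / reps
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_scan_with_threshold_flags(self, rng):
        g = _balanced_genotypes(40).astype(float)
        G = pd.DataFrame({"causal": g, "null": rng.permutation(g)})
        y = rng.normal(0, 1, 120) + 1.0 * g
        res = scan_with_threshold(y, G, n_perm=200, alpha=0.05, seed=0)
        assert bool(res.table.set_index("snp").loc["causal", "significant"])


class TestGenotypeVector:
    def test_codes_validated_and_counted(self):
        gv = GenotypeVector(np.array([1.0, 0, -1, np.nan, 1]), snp_id="rs1")
        assert gv.class_counts() == {1: 2, 0: 1, -1: 1}
        with pytest.raises(ValueError, match="codes"):
            GenotypeVector(np.array([2.0, 0.0]))


def test_seasonal_difference_restricted_to_paired_hosts():
    df = pd.DataFrame(
        {"winter": [1.0, 2.0, np.nan], "summer": [0.5, np.nan, 3.0]},
        index=["a", "b", "c"],
    )
    diff = seasonal_difference(df)
    assert list(diff.index) == ["a"]
    assert diff["a"] == pytest.approx(0.5)
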