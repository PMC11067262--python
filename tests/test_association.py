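"""Regression cores vs independent oracles, transform properties, calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from hla_phenoscope import synthetic_data as sd
from hla_phenoscope.association import (inverse_normal_transform,
                                        logistic_assoc, omnibus_test,
                                        quantitative_assoc, residualize,
                                        run_phewas)
from hla_phenoscope.variant_encoding import (AminoAcidTable, build_catalogue)
from hla_phenoscope.io_qc import GenotypeMatrix


class TestInverseNormalTransform:
    def test_median_of_odd_distinct_sample_is_zero(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        z = inverse_normal_transform(x)
        assert z[np.argsort(x)[2]] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_order_isomorphic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 200)
        z = inverse_normal_transform(x)
        np.testing.assert_array_equal(np.argsort(x), np.argsort(z))

    def test_large_sample_standardized(self):
        rng = np.random.default_rng(1)
        z = inverse_normal_transform(rng.exponential(3, 10_000))
        assert abs(z.mean()) < 0.01
        assert abs(z.std() - 1) < 0.02

    def test_blom_formula_and_ties(self):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        z = inverse_normal_transform(x)
        expected_tie = stats.norm.ppf((2.5 - 0.375) / 4.25)
        assert z[1] == pytest.approx(expected_tie, abs=1e-12)
        assert z[1] == z[2]

    def test_missing_preserved_and_errors(self):
        z = inverse_normal_transform(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(z[1]) and not np.isnan(z[0])
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([2.0, 2.0, 2.0]))


def _toy_binary(n=20, seed=4):
    rng = np.random.default_rng(seed)
    d = rng.choice([0.0, 1.0, 2.0], n)
    cov = rng.normal(0, 1, (n, 2))
    logit = -0.5 + 0.8 * d + 0.3 * cov[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    if len(np.unique(y)) < 2:  # re-draw degenerate fixtures
        return _toy_binary(n, seed + 1)
    return d, y, cov


class TestLogisticAssoc:
    def test_matches_statsmodels_mle_oracle(self):
        d, y, cov = _toy_binary()
        res = logistic_assoc(d, y, cov)
        X = sm.add_constant(np.column_stack([d, cov]))
        fit = sm.Logit(y, X).fit(disp=0)
        assert res.effect == pytest.approx(fit.params[1], abs=1e-6)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-4)
        assert res.or_ == pytest.approx(np.exp(fit.params[1]), rel=1e-6)

    def test_ci_is_exp_of_wald_interval(self):
        d, y, cov = _toy_binary(seed=9)
        res = logistic_assoc(d, y, cov)
        assert res.ci_low == pytest.approx(np.exp(res.effect - 1.96 * res.se))
        assert res.ci_high == pytest.approx(np.exp(res.effect + 1.96 * res.se))

    def test_constant_dosage_rejected(self):
        _, y, cov = _toy_binary()
        with pytest.raises(ValueError, match="zero variance"):
            logistic_assoc(np.ones_like(y), y, cov)

    def test_single_class_rejected(self):
        d, _, cov = _toy_binary()
        with pytest.raises(ValueError, match="single class"):
            logistic_assoc(d, np.zeros_like(d), cov)

    def test_separation_triggers_firth(self):
        # dosage perfectly separates cases from controls
        d = np.array([0.0] * 10 + [2.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        res = logistic_assoc(d, y)
        assert res.method == "firth"
        assert np.isfinite(res.effect) and np.isfinite(res.se)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, reps = 400, 3000
        rejections = 0
        for _ in range(reps):
            d = rng.binomial(2, 0.3, n).astype(float)
            cov = rng.normal(0, 1, (n, 2))
            y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.3 * cov[:, 0])))
                 ).astype(float)
            try:
                rejections += logistic_assoc(d, y, cov).p < 0.05
            except ValueError:
                continue
        rate = rejections / reps
        # 0.05 +/- 3.5 binomial SDs at 3,000 replicates
        assert 0.036 <= rate <= 0.064


class TestQuantitativeAssoc:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 60
        d = rng.binomial(2, 0.4, n).astype(float)
        cov = rng.normal(0, 1, (n, 3))
        y = 0.4 * d + cov @ [0.2, -0.1, 0.3] + rng.normal(0, 1, n)
        res = quantitative_assoc(d, y, cov)
        # oracle: explicit two-stage normal equations
        C = np.column_stack([np.ones(n), cov])
        resid = y - C @ np.linalg.solve(C.T @ C, C.T @ y)
        z = inverse_normal_transform(resid)
        X = np.column_stack([np.ones(n), d])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        rss = ((z - X @ beta) ** 2).sum()
        se = np.sqrt(rss / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
        assert res.effect == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)

    def test_affine_invariance_of_raw_trait(self):
        rng = np.random.default_rng(6)
        n = 120
        d = rng.binomial(2, 0.3, n).astype(float)
        cov = rng.normal(0, 1, (n, 2))
        y = 0.2 * d + rng.normal(0, 1, n)
        a = quantitative_assoc(d, y, cov)
        b = quantitative_assoc(d, 7.3 * y - 11.0, cov)
        assert a.effect == pytest.approx(b.effect, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        n, reps = 300, 2000
        pvals = []
        for _ in range(reps):
            d = rng.binomial(2, 0.3, n).astype(float)
            cov = rng.normal(0, 1, (n, 2))
            y = 0.3 * cov[:, 0] + rng.normal(0, 1, n)
            pvals.append(quantitative_assoc(d, y, cov).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_dosage_rejected(self):
        y = np.random.default_rng(0).normal(0, 1, 50)
        with pytest.raises(ValueError, match="zero variance"):
            quantitative_assoc(np.full(50, 1.0), y, None)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(8)
        n = 50
        cov = rng.normal(0, 1, (n, 2))
        cov = np.column_stack([cov, cov[:, 0] * 2.0])  # exact collinearity
        with pytest.raises(ValueError, match="collinear.*c3"):
            quantitative_assoc(rng.binomial(2, 0.4, n).astype(float),
                               rng.normal(0, 1, n), cov,
                               covariate_names=["c1", "c2", "c3"])


def _residue_position(rng, n, probs):
    pool = rng.choice(len(probs), size=(n, 2), p=probs)
    return np.stack([(pool == k).sum(1) for k in range(len(probs))]).astype(float)


class TestOmnibus:
    def test_df_is_residues_minus_one(self):
        rng = np.random.default_rng(10)
        n = 300
        D = _residue_position(rng, n, [0.5, 0.3, 0.2])
        y = rng.normal(0, 1, n)
        res = omnibus_test(D, y, None, "quantitative")
        assert (res.n_residues, res.df) == (3, 2)
        D2 = _residue_position(rng, n, [0.6, 0.4])
        assert omnibus_test(D2, y, None, "quantitative").df == 1

    def test_df1_binary_omnibus_equals_biallelic_lrt(self):
        rng = np.random.default_rng(12)
        n = 400
        D = _residue_position(rng, n, [0.6, 0.4])
        cov = rng.normal(0, 1, (n, 2))
        y = (rng.random(n) < 0.5).astype(float)
        res = omnibus_test(D, y, cov, "binary")
        # oracle: direct logistic LRT on the non-reference residue dosage
        minor = int(np.argmin(D.sum(axis=1)))
        X0 = sm.add_constant(cov)
        X1 = sm.add_constant(np.column_stack([cov, D[minor]]))
        ll0 = sm.Logit(y, X0).fit(disp=0).llf
        ll1 = sm.Logit(y, X1).fit(disp=0).llf
        lrt_p = stats.chi2.sf(2 * (ll1 - ll0), 1)
        assert res.p == pytest.approx(lrt_p, abs=1e-9)

    def test_statistic_nonnegative_and_planted_effect_detected(self):
        rng = np.random.default_rng(13)
        n = 2000
        D = _residue_position(rng, n, [0.5, 0.3, 0.2])
        y = 0.3 * D[2] + rng.normal(0, 1, n)
        res = omnibus_test(D, y, None, "quantitative")
        assert res.statistic >= 0
        assert res.p < 1e-8

    def test_collinear_residue_dropped_with_df_reduction(self):
        rng = np.random.default_rng(14)
        n = 200
        D2 = _residue_position(rng, n, [0.6, 0.4])
        D = np.vstack([D2, D2[1]])  # duplicated residue row
        y = rng.normal(0, 1, n)
        with pytest.warns(UserWarning, match="collinear"):
            res = omnibus_test(D, y, None, "quantitative",
                               residues=["A", "R", "N"])
        assert res.df == 1
        assert len(res.dropped_residues) == 1

    def test_null_calibration_quick(self):
        rng = np.random.default_rng(15)
        n, reps = 500, 600
        rej = 0
        for _ in range(reps):
            D = _residue_position(rng, n, [0.5, 0.3, 0.2])
            y = rng.normal(0, 1, n)
            rej += omnibus_test(D, y, None, "quantitative").p < 0.05
        # 0.05 +/- 3.5 binomial SDs at 600 replicates
        assert 0.019 <= rej / reps <= 0.081


def _phewas_fixture(n=5000, seed=20, or_effect=2.0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    hap = rng.random((n, 2)) < 0.25
    causal = hap.sum(1).astype(float)
    snvs = rng.binomial(2, rng.uniform(0.2, 0.8, 8), size=(n, 8)).astype(float)
    gm = GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame({
            "chrom": "6", "pos": 31_000_000 + np.arange(8) * 500,
            "id": [f"rs{j}" for j in range(8)], "ref": "A", "alt": "G"}),
        dosage=snvs)
    calls = pd.DataFrame({
        "sample": samples, "gene": "HLA-B",
        "allele1": np.where(hap[:, 0], "B*58:01", "B*40:01"),
        "allele2": np.where(hap[:, 1], "B*58:01", "B*40:01")})
    aa = AminoAcidTable(sequences={"B*58:01": "Q", "B*40:01": "H"})
    cat = build_catalogue(samples, snv_gm=gm, calls=calls, aa_table=aa)
    effects = [sd.EffectSpec("disease", "binary", "B*58:01",
                             np.log(or_effect), prevalence=0.1)]
    pheno = sd.simulate_phenotypes({"B*58:01": causal}, effects, n, seed=seed,
                                   sample_ids=samples)
    return cat, pheno


class TestRunPhewas:
    def test_planted_effect_is_top_signal(self):
        cat, pheno = _phewas_fixture()
        assoc, omni = run_phewas(cat, pheno, binary_traits=["disease"])
        top = assoc.sort_values("p").iloc[0]
        assert top["variant_id"] in ("HLA-B*58:01", "HLA-B-Q1")
        assert top["gws"]
        # recovered OR close to the planted 2.0
        assert assoc.set_index("variant_id").loc["HLA-B*58:01", "or_"] == \
            pytest.approx(2.0, rel=0.15)

    def test_row_accounting_and_null_gws(self):
        rng = np.random.default_rng(30)
        n = 800
        samples = [f"s{i}" for i in range(n)]
        snvs = rng.binomial(2, rng.uniform(0.2, 0.8, 40), (n, 40)).astype(float)
        gm = GenotypeMatrix(
            samples=samples,
            variants=pd.DataFrame({
                "chrom": "6", "pos": 31_000_000 + np.arange(40) * 100,
                "id": [f"rs{j}" for j in range(40)], "ref": "A", "alt": "G"}),
            dosage=snvs)
        cat = build_catalogue(samples, snv_gm=gm)
        pheno = sd.simulate_phenotypes(
            {}, [sd.EffectSpec(f"q{t}", "quantitative", None, 0.0)
                 for t in range(5)], n, seed=31, sample_ids=samples)
        assoc, _ = run_phewas(cat, pheno,
                              quantitative_traits=[f"q{t}" for t in range(5)])
        assert len(assoc) == 40 * 5
        assert assoc["gws"].sum() == 0

    def test_single_class_trait_skipped_with_warning(self):
        cat, pheno = _phewas_fixture(n=300, seed=40)
        pheno = pheno.copy()
        pheno["empty"] = 0.0
        with pytest.warns(UserWarning, match="single class"):
            assoc, _ = run_phewas(cat, pheno, binary_traits=["empty"])
        assert len(assoc) == 0
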