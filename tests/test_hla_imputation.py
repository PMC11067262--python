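"""Attribute-bagging training, posterior imputation, validation, serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hla_phenoscope import hla_imputation as hi
from hla_phenoscope import synthetic_data as sd


@pytest.fixture(scope="module")
def perfect_model(perfect_pool_mod, perfect_cohort_mod):
    gm, typing = perfect_cohort_mod
    return hi.train_model(gm, typing, "HLA-A", resolution=4,
                          n_classifiers=5, seed=3)


@pytest.fixture(scope="module")
def perfect_pool_mod():
    return sd.simulate_reference_pool(
        n_haplotypes=200, n_snps=16, alleles_per_gene=2,
        tagging_strength=1.0, seed=1, genes=("HLA-A",))


@pytest.fixture(scope="module")
def perfect_cohort_mod(perfect_pool_mod):
    return sd.simulate_cohort(perfect_pool_mod, 150, seed=2)


def _truth_map(typing):
    return {r["sample"]: tuple(sorted((r["allele1"], r["allele2"])))
            for _, r in typing.iterrows()}


class TestTrainModel:
    def test_requested_classifier_count_honored(self, perfect_model):
        assert len(perfect_model.classifiers) == 5

    def test_perfect_tagging_concentrates_frequency_mass(self, perfect_model):
        for clf in perfect_model.classifiers:
            assert clf.oob_accuracy == pytest.approx(1.0)
            table = clf.freq_table
            assert sum(table.values()) == pytest.approx(1.0, abs=1e-9)
            # mass concentrated on pattern-allele pairs that identify alleles
            by_allele = {}
            for (pattern, allele), f in table.items():
                by_allele.setdefault(allele, 0.0)
                by_allele[allele] += f
            assert len(by_allele) == 2

    def test_resolution_below_requested_rejected(self, perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        with pytest.raises(ValueError, match="resolution below 6"):
            hi.train_model(gm, typing, "HLA-A", resolution=6, n_classifiers=2)

    def test_em_matches_brute_force_likelihood_oracle(self):
        # two SNPs, two alleles, known phased haplotype frequencies
        rng = np.random.default_rng(8)
        haps = [((0, 0), "A*01:01"), ((1, 1), "A*02:01"),
                ((1, 0), "A*01:01"), ((0, 1), "A*02:01")]
        true_f = np.array([0.45, 0.3, 0.15, 0.1])
        n = 120
        draws = rng.choice(4, size=(n, 2), p=true_f)
        geno = np.array([[haps[i][0][k] + haps[j][0][k] for k in range(2)]
                         for i, j in draws], dtype=float)
        pairs = [tuple(sorted((haps[i][1], haps[j][1]))) for i, j in draws]
        patterns, alleles, freqs = hi.em_joint_frequencies(geno, pairs)

        def negll(theta):
            e = np.exp(theta - theta.max())
            f = e / e.sum()
            ll = 0.0
            for (g1, g2), (a1, a2) in zip(geno, pairs):
                tot = 0.0
                for i, j in itertools.product(range(4), range(4)):
                    (p1, al1), (p2, al2) = haps[i], haps[j]
                    if (p1[0] + p2[0], p1[1] + p2[1]) != (g1, g2):
                        continue
                    if {al1, al2} != {a1, a2} and (al1, al2) != (a1, a2):
                        continue
                    if tuple(sorted((al1, al2))) != (a1, a2):
                        continue
                    tot += f[i] * f[j]
                ll += np.log(tot)
            return -ll

        best = None
        for _ in range(10):
            res = minimize(negll, rng.normal(0, 1, 4), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-13,
                                    "maxiter": 40000})
            if best is None or res.fun < best.fun:
                best = res
        e = np.exp(best.x - best.x.max())
        oracle = e / e.sum()
        est = {}
        for p, a, f in zip(patterns, alleles, freqs):
            est[(tuple(int(b) for b in p), a)] = est.get(
                (tuple(int(b) for b in p), a), 0.0) + f
        for k, (pat, allele) in enumerate(haps):
            assert est.get((pat, allele), 0.0) == pytest.approx(
                oracle[k], abs=1e-6)

    def test_monomorphic_flank_rejected(self, perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        gm2 = gm.subset()
        gm2.dosage[:, :] = 1.0
        with pytest.raises(ValueError, match="polymorphic"):
            hi.train_model(gm2, typing, "HLA-A", n_classifiers=1)


class TestImpute:
    def test_deterministic_recovery(self, perfect_model, perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        calls = hi.impute(perfect_model, gm)
        truth = _truth_map(typing)
        assert calls["called"].all()
        for _, r in calls.iterrows():
            assert (r["allele1"], r["allele2"]) == truth[r["sample"]]

    def test_posteriors_normalized(self, perfect_model, perfect_cohort_mod):
        gm, _ = perfect_cohort_mod
        clf = perfect_model.classifiers[0]
        cols = [list(gm.variants["id"]).index(s) for s in clf.snp_ids]
        posts = hi._pair_posteriors(clf, gm.dosage[:, cols])
        for post in posts:
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_threshold_monotonicity_and_called_flag(self, perfect_model,
                                                    perfect_cohort_mod):
        gm, _ = perfect_cohort_mod
        rates = []
        for thr in (0.9, 0.5, 0.3):
            calls = hi.impute(perfect_model, gm, call_threshold=thr)
            rates.append(calls["called"].mean())
            assert (calls["called"] == (calls["posterior"] >= thr)).all()
        assert rates == sorted(rates)  # lowering threshold never lowers rate

    def test_no_snp_overlap_rejected(self, perfect_model, perfect_cohort_mod):
        gm, _ = perfect_cohort_mod
        gm2 = gm.subset()
        gm2.variants["id"] = [f"other{j}" for j in range(gm2.n_variants)]
        with pytest.raises(ValueError, match="overlap"):
            hi.impute(perfect_model, gm2)

    def test_missing_snps_marginalized(self, perfect_model, perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        gm2 = gm.subset()
        used = {s for c in perfect_model.classifiers for s in c.snp_ids}
        j = list(gm2.variants["id"]).index(sorted(used)[0])
        gm2.dosage[:5, j] = np.nan
        calls = hi.impute(perfect_model, gm2)
        assert len(calls) == gm2.n_samples  # subjects kept, not dropped

    def test_ensemble_not_worse_than_worst_classifier(self, perfect_model,
                                                      perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        truth = _truth_map(typing)

        def accuracy(model):
            calls = hi.impute(model, gm, call_threshold=0.0)
            return np.mean([hi.pair_match_count(
                truth[r["sample"]], (r["allele1"], r["allele2"])) / 2
                for _, r in calls.iterrows()])

        worst = min(
            accuracy(hi.ImputationModel(
                gene=perfect_model.gene, resolution=perfect_model.resolution,
                classifiers=[c], allele_list=perfect_model.allele_list))
            for c in perfect_model.classifiers)
        assert accuracy(perfect_model) >= worst - 1e-12


class TestInternalValidation:
    def test_split_arithmetic(self):
        assert hi.split_sizes(845, 0.7) == (592, 253)
        assert hi.split_sizes(10, 0.7) == (7, 3)

    def test_deterministic_cohort_perfect_scores(self, perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        acc, cr = hi.internal_validation(gm, typing, "HLA-A", resolution=4,
                                         n_classifiers=4, seed=7)
        assert acc == pytest.approx(1.0)
        assert cr == pytest.approx(1.0)

    def test_heterozygote_half_credit(self):
        assert hi.pair_match_count(("a", "b"), ("a", "c")) == 1
        assert hi.pair_match_count(("a", "a"), ("a", "b")) == 1
        assert hi.pair_match_count(("a", "b"), ("b", "a")) == 2
        assert hi.pair_match_count(("a", "a"), ("b", "b")) == 0

    def test_too_few_subjects_rejected(self, perfect_cohort_mod):
        gm, typing = perfect_cohort_mod
        few = typing[typing["sample"].isin(gm.samples[:5])]
        with pytest.raises(ValueError, match=">= 10"):
            hi.internal_validation(gm, few, "HLA-A")


class TestSerialization:
    def test_round_trip_preserves_model_and_calls(self, perfect_model,
                                                  perfect_cohort_mod, tmp_path):
        gm, _ = perfect_cohort_mod
        path = str(tmp_path / "model.json")
        hi.serialize_model(perfect_model, path)
        back = hi.load_model(path)
        assert back.gene == perfect_model.gene
        assert back.resolution == perfect_model.resolution
        assert back.allele_list == perfect_model.allele_list
        for a, b in zip(perfect_model.classifiers, back.classifiers):
            assert a.snp_ids == b.snp_ids
            np.testing.assert_array_equal(a.patterns, b.patterns)
            np.testing.assert_array_equal(a.freqs, b.freqs)  # full precision
        pd.testing.assert_frame_equal(hi.impute(perfect_model, gm),
                                      hi.impute(back, gm))

    def test_truncated_file_is_error_not_crash(self, perfect_model, tmp_path):
        path = tmp_path / "model.json"
        hi.serialize_model(perfect_model, str(path))
        path.write_text(path.read_text()[: 50])
        with pytest.raises(ValueError, match="corrupt|truncated"):
            hi.load_model(str(path))

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format_version": 99, "classifiers": []}')
        with pytest.raises(ValueError, match="version"):
            hi.load_model(str(path))
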