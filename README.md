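# hla-phenoscope

An analysis chain for the HLA region (chr6: 28,510,120–33,480,577,
GRCh38): train an attribute-bagging HLA imputation reference panel from
paired SNP genotypes and sequencing-based typings, impute classical
alleles with posterior probabilities, encode amino-acid polymorphisms,
run a phenome-wide association scan with a multiallelic omnibus test,
fine-map signals by forward conditional regression, estimate
region-wide heritability and genetic correlations by Haseman-Elston
regression, phase multilocus haplotype frequencies by EM, and summarize
carriers of adverse-drug-reaction-associated alleles.  A bundled
synthetic-cohort generator makes every stage testable without any
external download.

It is written for statistical geneticists who want the individual
building blocks (each stage is an importable, tested library function)
as well as for readers who want to run the chain end to end on
synthetic data.

## The statistics at the core

**Imputation.** A reference panel for one gene is an ensemble of
classifiers.  Each classifier is trained on a bootstrap sample of typed
subjects: a SNP subset is grown greedily from the gene's 500-kb flank,
adding the SNP that maximizes out-of-bag allele-prediction accuracy,
and the joint frequencies f(h, a) of SNP-subset haplotype pattern h and
HLA allele a are estimated by EM over the unphased data.  A subject's
allele-pair posterior is

P(a₁a₂ | g) ∝ Σ f(h₁, a₁)·f(h₂, a₂) over phase-consistent (h₁, h₂),

averaged across classifiers; genotypes are *called* at posterior ≥ 0.5.
Accuracy is scored per allele (each subject contributes two).

**PheWAS.** Binary traits: additive logistic regression with covariates
sex, age, age², PC1–PC10 (Firth fallback on separation).  Quantitative
traits: covariate residuals, rank-based inverse-normal transform (Blom),
OLS on dosage.  Each multiallelic amino-acid position gets an omnibus
likelihood-ratio test of all residues against the covariate-only null,
χ² with n−1 degrees of freedom for n residues.  Genome-wide significance
is p < 5×10⁻⁸.

**Conditional fine-mapping.** Iteratively condition on the top signal
*plus every HLA allele and amino-acid polymorphism at r² ≥ 0.7 with it*
until no variant stays significant; r² = 1 companions are reported as
co-top signals.

**Heritability.** With GRM A from standardized catalogue dosages,
univariate Haseman-Elston regression of y_i·y_j on A_ij (pairs i<j)
estimates h²; bivariate HE on symmetrized cross-products estimates the
genetic covariance and r_g = cov_g/√(h²₁h²₂), with block-jackknife
standard errors and a Benjamini-Hochberg-filtered correlation network.

**Haplotypes.** Standard multilocus EM over unordered genotypes with
progressive gene insertion and pruning, initialized from marginal
allele frequencies.

See `docs/methods.md` for assumptions, tunable parameters, numerical
choices, and limitations.

## Worked example

The numbered drivers under `analysis/` run the chain on a synthetic
cohort of 1,000 subjects (2 genes × 4 alleles, strong LD, one planted
binary and one planted quantitative effect) and narrate what they find:

```sh
cd analysis
python 01_simulate_cohort.py
python 03_train_impute_validate.py
python 05_run_phewas.py
python 06_conditional_finemap.py
```

prints, among other things:

```
planted effects: {'disease': 'B*01:01', 'biomarker': 'A*01:01'}
  HLA-A: hold-out per-allele accuracy 99.2%, call rate 99.7%
  HLA-B: hold-out per-allele accuracy 99.3%, call rate 100.0%
genome-wide significant associations: 16
  biomarker: top signal HLA-A*01:01 (beta 0.545, p = 3.66e-37)
  disease: top signal HLA-B*01:01 (OR 3.39, p = 1.78e-21)
2 independent signals across 2 traits:
  biomarker step 1: HLA-A*01:01 (p = 3.66e-37); ... complete-LD companions: ['HLA-A-A9']
  disease step 1: HLA-B*01:01 (p = 1.78e-21); ... complete-LD companions: ['HLA-B-A9']
```

Reading this: the hold-out validation confirms the panel imputes 4-digit
alleles nearly perfectly at this LD strength; the scan's top signal for
each trait is exactly the planted causal allele (with its perfect-LD
residue variant reported as a complete-LD companion); and the forward
conditional analysis collapses the 16 correlated genome-wide-significant
associations onto the 2 truly independent signals.

The same pieces are available directly from the library:

```python
from hla_phenoscope import synthetic_data as sd
from hla_phenoscope import hla_imputation as hi

pool = sd.simulate_reference_pool(**sd.easy_preset(seed=11))
gm, typing = sd.simulate_cohort(pool, 2000, seed=12)
acc, call_rate = hi.internal_validation(gm, typing, "HLA-B",
                                        resolution=4, n_classifiers=20,
                                        seed=14)
```

## Layout

```
src/hla_phenoscope/   the library (io_qc, synthetic_data, hla_imputation,
                      variant_encoding, association, conditional,
                      heritability, haplotypes, pgx, pipeline)
analysis/             numbered narrative drivers over the library
tests/                pytest suite incl. the acceptance tests
scripts/acceptance.py headline-quantity reproduction
docs/methods.md       the methods note
```
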