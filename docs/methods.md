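# Methods

This note documents the statistical procedures implemented in
`hla_phenoscope`, the choices made where the design was genuinely open,
and what the bundled synthetic data can and cannot demonstrate.

## Genotype QC (`io_qc`)

Variants are excluded on call rate < 0.98, minor allele frequency
< 0.05, or a Hardy-Weinberg exact-test p below 1e-6; samples on call
rate < 0.98, heterozygosity outside mean ± 3 SD, or pairwise identity by
descent (PI_HAT) above 0.1875.  The MHC window is chromosome 6,
28,510,120–33,480,577 bp (GRCh38), inclusive at both ends; all
coordinates in the package are 1-based inclusive.

The HWE test is the plain two-sided exact test (no mid-p): the
conditional distribution of the heterozygote count given the allele
counts is enumerated exactly and all outcomes at most as probable as the
observed one are summed.  Missing dosages leave both the MAF and the
HWE numerators and denominators.

PI_HAT is the classic method-of-moments estimator: observed counts of
identity-by-state 0/1/2 per pair are equated with their expectations
under IBD state 0/1/2 given observed allele frequencies, solving for
P(IBD = z) with clamping to [0, 1], and PI_HAT = P(1)/2 + P(2).  The
small-sample bias corrections some implementations add are omitted.
Because the estimator is meaningless on a handful of correlated
variants, the IBD filter is skipped (with a warning) when fewer than 100
variants are available; it is intended to run on genome-wide data.  When
a pair exceeds the threshold, the member with the lower call rate is
dropped (tie: the lexicographically larger sample ID).  Heterozygosity
bounds use all supplied variants (genome-wide when given genome-wide
input).  The sex check runs only when both reported and inferred sex are
supplied, and is silently skipped otherwise.

PLINK bed/bim/fam I/O is implemented directly (the 2-bit SNP-major
codec), with A1 treated as the ALT/dosage-counted allele; VCF I/O goes
through cyvcf2 and accepts only biallelic records.

## Synthetic cohorts (`synthetic_data`)

The generator produces the statistical structure the analysis chain
assumes, not realistic MHC sequence.  Each HLA allele receives a one-hot
"signature" among its gene's SNPs; a haplotype carrying the allele
copies each signature SNP with probability `tagging_strength` and
otherwise draws a fair coin, so tagging 1.0 makes the allele perfectly
predictable and tagging 0 destroys all LD.  Background SNPs are
independent with frequencies uniform on (0.15, 0.85).  Allele
frequencies per gene follow a decreasing geometric spectrum (ratio 0.7),
putting the dominant allele near 0.2–0.4 — the order of magnitude of
common classical alleles.  Cohorts are random unions of two pool
haplotypes, so Hardy-Weinberg holds at the haplotype level by
construction.  Gene anchors sit at GRCh38-like positions inside the MHC
window so region extraction and 500-kb flank logic run unmodified.

Phenotypes: covariates are sex (31.7% male), age ~ N(50.5, 10.58²)
clipped to [30, 70], age², and ten standard-normal PCs, with small fixed
covariate effects (sex 0.2, centred age 0.01/yr, PC1 0.05) so covariate
adjustment is genuinely exercised.  Binary traits follow an additive
logit model whose intercept is calibrated by bisection to hit the stated
prevalence; quantitative traits are additive with Gaussian residuals.
Amino-acid tables give each gene a shared base sequence plus a
family-determined position (2-digit relatives share it), a strictly
biallelic position, and a position with one residue per allele, so
omnibus tests with df ≥ 2 exist whenever a gene has ≥ 3 alleles.

Two presets are used throughout: the *benchmark* preset (2 genes × 4
alleles, tagging 0.95) deliberately stresses the classifier ensemble —
each haplotype has an ~18% chance of carrying at least one corrupted
signature SNP — while pipeline demonstrations default to tagging 0.99,
the operating point of a well-powered reference panel (call rates
0.95–1.0).  Planted demonstration effects are sized for near-certain
power at p < 5e-8 at desk-scale n (z ≈ 7–9), so recovery checks are
deterministic properties rather than coin flips.

What passing tests do *not* show about real data: no recombination maps,
no population structure beyond injected PCs, no genotyping error model,
no rare-allele tail, and far fewer alleles per gene than reality.

## HLA imputation (`hla_imputation`)

A reference panel for one gene/resolution is an attribute-bagging
ensemble (default 100 classifiers) trained on subjects with both SNP
genotypes (within a 500-kb flank of the gene anchor) and HLA typings.
Per classifier: a bootstrap sample of subjects is drawn; the SNP subset
grows greedily over the whole flank, each step adding the SNP that
maximizes out-of-bag per-allele prediction accuracy and stopping when no
remaining SNP improves it (cap 15 SNPs, which bounds the EM state
space); the joint frequencies of (SNP-subset haplotype pattern, HLA
allele) are then fitted by EM over the unphased data.

The EM treats each subject's phase assignment as the hidden variable:
ordered pairs of (pattern, allele) haplotypes consistent with the
subject's dosages and unordered allele pair.  Initialization is
phase-naive counting; convergence at log-likelihood change < 1e-7 or 500
iterations (looser during greedy search: 1e-4/30); haplotypes below 1e-8
are pruned and frequencies renormalized, with each subject's best
expansion always retained.  The log-likelihood is non-decreasing by
construction and asserted in tests.

Imputation computes, per classifier, P(allele pair | SNP genotype) by
summing frequency products over phase-consistent pattern pairs and
normalizing over allele pairs; posteriors are averaged across
classifiers (a classifier whose table cannot explain a genotype abstains
for that subject), the best pair is the argmax (ties broken by
lexicographic allele-pair order), and a genotype is *called* when its
posterior reaches the threshold (default 0.5).  SNPs missing at
imputation time are marginalized over the frequency table rather than
dropping the subject.

Hold-out validation splits subjects train:validation at 7:3
(train size = round(0.7·n), e.g. 845 → 592/253), reports the call rate
and the per-allele accuracy among called subjects: each subject
contributes two alleles matched as unordered pairs, so a heterozygote
with one correct allele scores 1/2.  Per-allele (rather than
per-genotype) scoring is the convention of attribute-bagging HLA
imputation software and is stated in the report header.  A validation
allele absent from training still counts against accuracy, with a
warning.  Six-digit models require three-field typings; lower-resolution
requests truncate trailing fields.

Models serialize to versioned JSON with `repr`-precision frequencies, so
a round-trip reproduces imputation results bit-for-bit.

## Variant catalogue (`variant_encoding`)

The PheWAS catalogue unifies biallelic SNVs, indels, HLA-allele dosages
(0/1/2 copies; uncalled subjects missing), and amino-acid residue
presence variants, plus multiallelic amino-acid positions.  Translation
is keyed at 4-digit (protein-level) alleles — synonymous third-field
differences cannot change the sequence — and uses called genotypes only,
so uncalled subjects propagate into the missing-rate filter.  Every
position with ≥ 2 observed residues is recorded as a position (omnibus
target) and each of its residues becomes a presence variant named
`GENE-<residue><position>` (e.g. `HLA-B-Q94`); positions display as
`GENE pos <n>`.  Residue dosages at a position sum to 2 for every
fully-called subject.

Post-imputation QC: HLA alleles and biallelic residue variants are
dropped at missing rate > 0.05 or MAF < 0.01; multiallelic positions at
missing rate > 0.05 only; SNVs/indels pass through untouched (they were
QCed upstream).  LD r² is the squared Pearson correlation of dosages
over pairwise-complete subjects (undefined on zero variance).
SNVs/indels are tagged with every gene having an HLA allele or residue
variant at r² ≥ 0.7 (boundary inclusive, possibly several genes, '-'
when none); LD for tagging and companion sets is computed on all
subjects, not cases only.

## Association scan (`association`)

Binary traits: additive logistic regression with covariates sex, age,
age², PC1–PC10, Wald tests, and a Firth (Jeffreys-penalized) fallback
whenever the unpenalized Newton fit separates or fails to converge —
routine when rare alleles meet rare traits.  Quantitative traits are
residualized on the covariates, rank-based inverse-normal transformed
(Blom offset 3/8, average ranks for ties), and tested against dosage by
OLS; the rank transform makes results invariant to affine rescaling of
the raw trait.  These are plain covariate-adjusted single-variant tests:
a whole-genome ridge/LOCO stage is deliberately not reproduced, because
an HLA-only region offers no leave-one-chromosome-out genome to build it
from.

The omnibus test at an amino-acid position compares the covariate-only
null against the null plus dosages of all residues except the most
frequent one (tie: lexicographically first), giving a likelihood-ratio
statistic that is chi-square with df = n − 1 for n residues.  For
quantitative traits the LRT runs on the same transformed residuals as
the biallelic tests (statistic n·log(RSS₀/RSS₁)), for comparability; a
df-1 omnibus then equals the single-residue LRT exactly.  Collinear
residue columns are dropped with a warning and the df reduced.
Significance is the fixed genome-wide line p < 5e-8, with no further
multiple-testing correction.

## Conditional fine-mapping (`conditional`)

For each trait with a genome-wide-significant signal: select the top
remaining variant (ties: smaller p, then lexicographic id), add it *and
every HLA allele and amino-acid polymorphism at r² ≥ 0.7 with it* to the
covariate set, rescan, and repeat until nothing reaches significance
(guard: 20 iterations).  SNV/indel companions are reported but never
conditioned on.  Variants at r² = 1 (within 1e-12) with a selected
signal are listed as co-top signals.  For quantitative traits the
conditioning dosages enter the final-stage regression alongside the test
dosage; the covariate residualization is not redone per step, keeping
the null model fixed across iterations.  Collinear conditioning columns
(checked jointly with the intercept) are dropped with a warning, and
exactly-singular conditional fits are skipped rather than propagating
NaNs.

## Heritability (`heritability`)

The GRM standardizes each dosage to mean 0, variance 1 under its
observed allele frequency and averages products over the variants
non-missing in both subjects.  Univariate Haseman-Elston regression
regresses phenotype cross-products y_i·y_j on GRM entries over pairs
i < j (diagonal excluded, intercept included); the slope is h².
Bivariate HE regresses symmetrized cross-trait products
(y1_i·y2_j + y1_j·y2_i)/2, giving the genetic covariance and
r_g = cov_g/√(h²₁·h²₂), clamped to [−1, 1] with the clamp recorded and
undefined when either h² ≤ 0.  Standard errors come from a
delete-one-block jackknife over subjects (default 100 blocks), computed
in closed form from per-block pair sums; p-values use the normal
approximation on the jackknife SE of r_g itself.  Binary traits enter on
the observed 0/1 scale (no liability transform; flagged in output).
Heritabilities print as percentages with two decimals.  FDR control for
the correlation network is Benjamini-Hochberg across all tested pairs;
edges are pairs with q < 0.05, weighted by signed r_g, and only traits
with at least one edge appear.

## Haplotype frequencies (`haplotypes`)

Multilocus frequencies come from the standard EM over unordered
genotypes, with genes inserted progressively in the requested order and
haplotypes below 1e-7 pruned between insertions (1e-6 at output), so the
state space stays restricted to combinations compatible with at least
one subject — the usual progressive-insertion practice, without which
eight genes are infeasible.  Initialization is the product of marginal
allele frequencies; convergence at log-likelihood change < 1e-8 (1000
iterations max); the log-likelihood is asserted non-decreasing.  Only
subjects called at all requested genes enter (others are excluded with a
warning and counted).  The five-gene order A-C-B-DRB1-DQB1 is provided
as a constant for cross-population comparisons.  Ranking is by frequency
with lexicographic tie-breaks, formatted as '-'-joined allele names.

## ADR carrier screening (`pgx`)

A carrier has ≥ 1 copy of the allele among subjects called at its gene;
the denominator is those called subjects and is recorded per row.
Homozygotes count once as carriers but twice in the allele-frequency
numerator, so frequency ≤ carrier fraction ≤ 2·frequency always holds.
The HWE-expected carrier fraction 1 − (1 − p)² is reported alongside as
a consistency diagnostic.  The bundled allele list is an annotation
table (drugs, reactions, populations) only; no risk modelling is done.

## Pipeline (`pipeline`)

`RunConfig` defaults are exactly the analysis constants (QC
0.98/0.05/1e-6; 100 classifiers; 500-kb flank; call threshold 0.5;
post-imputation 0.05/0.01; GWS 5e-8; LD 0.7; FDR 0.05).  One run seed
derives per-stage sub-seeds through a fixed affine scheme (all below
2³¹), so stages are individually reproducible and a rerun with the same
config is bit-identical; the manifest records per-stage output digests.
The library functions and the numbered `analysis/` drivers are the
interface; there is no separate command-line binary.

## Problem sizes in the test and acceptance suites

Calibration and recovery checks run at sizes chosen to keep the full
suite under a couple of minutes while leaving Monte-Carlo error well
inside the asserted bands: omnibus null calibration at n = 1,000
subjects × 5,000 replicates; imputation recovery on the benchmark preset
at n = 2,000 with 20 classifiers; HE recovery at n = 2,000 subjects ×
500 variants; conditional recovery at n = 5,000; logistic type-I error
at 3,000 replicates with the corresponding ±3.5-SD binomial band.
Carrier arithmetic uses the full published cohort composition
(n = 59,448) since it is pure counting.

## Known limitations

- The IBD estimator lacks small-sample corrections and needs many
  quasi-independent variants; it is a QC utility, not a relatedness
  research tool.
- Firth p-values are Wald-based on the penalized fit; profile-likelihood
  intervals are not implemented.
- The HE jackknife assumes exchangeable subjects; family structure would
  require clustered blocks.
- Six-digit imputation requires fully three-field typings and does not
  mix resolutions within a gene.
- The synthetic generator's LD model (one-hot signatures plus noise) is
  far simpler than real MHC haplotype structure; accuracy numbers on it
  are analogues, not forecasts, of performance on real panels.
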