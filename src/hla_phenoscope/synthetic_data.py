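"""Synthetic MHC-like cohorts for exercising the analysis chain.

The generator emulates the statistical structure the downstream stages
assume: phased SNP haplotypes in tunable LD with multi-gene HLA alleles at
realistic frequencies, Hardy-Weinberg genotypes by random union of
haplotypes, amino-acid tables with family structure, and phenotypes with
configurable additive HLA effects plus sex/age/PC covariates.

Every HLA allele is given a one-hot core SNP signature inside its gene's
window; a haplotype carrying the allele copies each signature SNP with
probability ``tagging_strength`` and otherwise draws a fair coin, so
``tagging_strength = 1`` makes the allele perfectly predictable and
``tagging_strength = 0`` destroys all LD.  All randomness flows through a
single seeded generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix
from .variant_encoding import AminoAcidTable

#: GRCh38-like anchor positions (bp) inside the chromosome-6 MHC window
GENE_ANCHORS = {
    "HLA-A": 29_942_554,
    "HLA-C": 31_268_749,
    "HLA-B": 31_353_875,
    "HLA-DRB1": 32_578_775,
    "HLA-DQA1": 32_628_179,
    "HLA-DQB1": 32_659_467,
    "HLA-DPA1": 33_064_569,
    "HLA-DPB1": 33_075_990,
}

_RESIDUES = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class ReferencePool:
    """Phased SNP haplotypes, each labelled with one HLA allele per gene."""

    genes: list[str]
    snp_positions: np.ndarray  # 1-based bp, strictly increasing
    snp_ids: list[str]
    hap_snps: np.ndarray = field(repr=False)     # H x S, 0/1
    hap_alleles: np.ndarray = field(repr=False)  # H x G allele text
    frequencies: np.ndarray = field(repr=False)  # H, sums to 1
    gene_windows: dict[str, np.ndarray] = field(default_factory=dict)
    signature_snps: dict[str, dict[str, int]] = field(default_factory=dict)
    chrom: str = "6"

    def __post_init__(self) -> None:
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies do not sum to 1")
        if self.hap_snps.shape != (len(self.frequencies), len(self.snp_positions)):
            raise ValueError("haplotype SNP matrix shape mismatch")

    def gene_alleles(self, gene: str) -> list[str]:
        g = self.genes.index(gene)
        return sorted(set(self.hap_alleles[:, g]))


def _allele_name(gene: str, index: int) -> str:
    """Synthetic 4-digit names with 2-digit family structure: 01:01, 01:02, 02:01..."""
    family, member = index // 2 + 1, index % 2 + 1
    return f"{gene.removeprefix('HLA-')}*{family:02d}:{member:02d}"


def allele_frequency_spectrum(n_alleles: int, ratio: float = 0.7) -> np.ndarray:
    """Decreasing geometric allele frequencies (dominant allele ~0.2-0.4)."""
    w = ratio ** np.arange(n_alleles)
    return w / w.sum()


def simulate_reference_pool(n_haplotypes: int = 500, n_snps: int = 40,
                            alleles_per_gene: int = 4,
                            tagging_strength: float = 0.95,
                            seed: int = 0,
                            genes: tuple[str, ...] = ("HLA-A", "HLA-B"),
                            ) -> ReferencePool:
    """Draw a pool of labelled haplotypes with tunable SNP-allele LD."""
    if not 0.0 <= tagging_strength <= 1.0:
        raise ValueError("tagging_strength must be in [0, 1]")
    if alleles_per_gene < 2:
        raise ValueError("need >= 2 alleles per gene")
    genes = list(genes)
    n_sig = alleles_per_gene * len(genes)
    if n_snps < n_sig:
        raise ValueError(
            f"n_snps={n_snps} < {n_sig} signature SNPs required")
    rng = np.random.default_rng(seed)
    per_gene = n_snps // len(genes)
    extra = n_snps - per_gene * len(genes)

    positions, snp_ids = [], []
    gene_windows: dict[str, np.ndarray] = {}
    signature: dict[str, dict[str, int]] = {}
    allele_names: dict[str, list[str]] = {}
    col = 0
    for g, gene in enumerate(genes):
        k = per_gene + (extra if g == len(genes) - 1 else 0)
        anchor = GENE_ANCHORS[gene]
        pos = anchor - 200_000 + np.arange(k) * (400_000 // max(k, 1))
        positions.extend(pos.tolist())
        snp_ids.extend(f"rs{gene.removeprefix('HLA-')}{j}" for j in range(k))
        gene_windows[gene] = np.arange(col, col + k)
        alleles = [_allele_name(gene, a) for a in range(alleles_per_gene)]
        allele_names[gene] = alleles
        signature[gene] = {a: col + j for j, a in enumerate(alleles)}
        col += k

    freqs = {g: allele_frequency_spectrum(alleles_per_gene) for g in genes}
    background_af = rng.uniform(0.15, 0.85, size=n_snps)
    hap_snps = (rng.random((n_haplotypes, n_snps)) < background_af).astype(np.int8)
    hap_alleles = np.empty((n_haplotypes, len(genes)), dtype=object)
    for g, gene in enumerate(genes):
        drawn = rng.choice(alleles_per_gene, size=n_haplotypes, p=freqs[gene])
        hap_alleles[:, g] = [allele_names[gene][a] for a in drawn]
        sig_cols = np.array([signature[gene][a] for a in allele_names[gene]])
        # one-hot signature, copied per SNP with probability tagging_strength
        target = np.zeros((n_haplotypes, len(sig_cols)), dtype=np.int8)
        target[np.arange(n_haplotypes), drawn] = 1
        copy = rng.random(target.shape) < tagging_strength
        noise = (rng.random(target.shape) < 0.5).astype(np.int8)
        hap_snps[:, sig_cols] = np.where(copy, target, noise)

    return ReferencePool(
        genes=genes,
        snp_positions=np.asarray(positions),
        snp_ids=snp_ids,
        hap_snps=hap_snps,
        hap_alleles=hap_alleles,
        frequencies=np.full(n_haplotypes, 1.0 / n_haplotypes),
        gene_windows=gene_windows,
        signature_snps=signature,
    )


def simulate_cohort(pool: ReferencePool, n_subjects: int, seed: int = 0
                    ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Random union of two pool haplotypes per subject (HWE by construction).

    Returns unphased dosages and the truth typing table
    (sample, gene, allele1, allele2) with alleles in sorted order.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool.frequencies), size=(n_subjects, 2),
                     p=pool.frequencies)
    dosage = (pool.hap_snps[idx[:, 0]] + pool.hap_snps[idx[:, 1]]).astype(float)
    samples = [f"S{i:06d}" for i in range(n_subjects)]
    variants = pd.DataFrame({
        "chrom": pool.chrom,
        "pos": pool.snp_positions,
        "id": pool.snp_ids,
        "ref": "A",
        "alt": "G",
    })
    gm = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    rows = []
    for i, s in enumerate(samples):
        for g, gene in enumerate(pool.genes):
            a1, a2 = sorted((pool.hap_alleles[idx[i, 0], g],
                             pool.hap_alleles[idx[i, 1], g]))
            rows.append((s, gene, a1, a2))
    typing = pd.DataFrame(rows, columns=["sample", "gene", "allele1", "allele2"])
    return gm, typing


@dataclass
class EffectSpec:
    """One planted additive effect of a variant dosage on a trait.

    ``effect`` is log-odds per dosage for binary traits and a per-dosage
    shift in residual-SD units for quantitative traits.
    """

    trait: str
    trait_type: str  # "binary" | "quantitative"
    target: str
    effect: float
    prevalence: float | None = None  # binary baseline case fraction
    sd: float = 1.0                  # quantitative residual SD

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError("binary trait needs prevalence in (0, 1)")


def simulate_covariates(n_subjects: int, rng: np.random.Generator,
                        n_pcs: int = 10) -> pd.DataFrame:
    """Sex (0/1), age ~ N(50.5, 10.58) clipped to [30, 70], age^2, PCs."""
    sex = (rng.random(n_subjects) < 0.317).astype(float)  # fraction male
    age = np.clip(rng.normal(50.5, 10.58, n_subjects), 30, 70).round(1)
    cov = pd.DataFrame({"sex": sex, "age": age, "age2": age * age})
    for k in range(1, n_pcs + 1):
        cov[f"PC{k}"] = rng.normal(0, 1, n_subjects)
    return cov


def typing_dosages(typing: pd.DataFrame, samples: list[str]
                   ) -> dict[str, np.ndarray]:
    """Allele-name -> 0/1/2 dosage vectors from a truth typing table."""
    out: dict[str, np.ndarray] = {}
    sidx = {s: i for i, s in enumerate(samples)}
    for _, row in typing.iterrows():
        i = sidx[row["sample"]]
        for a in (row["allele1"], row["allele2"]):
            out.setdefault(a, np.zeros(len(samples)))[i] += 1
    return out


# modest covariate effects so adjustment is genuinely exercised
_COVARIATE_EFFECTS = {"sex": 0.2, "age_centered": 0.01, "PC1": 0.05}


def simulate_phenotypes(targets: dict[str, np.ndarray],
                        effects: list[EffectSpec],
                        n_subjects: int, seed: int = 0,
                        sample_ids: list[str] | None = None,
                        n_pcs: int = 10) -> pd.DataFrame:
    """Phenotype + covariate table under additive dosage models.

    Binary: logit P(case) = intercept + sum(effect * dosage) + covariates,
    with the intercept calibrated so the marginal case fraction equals the
    stated prevalence.  Quantitative: y = sum(effect * dosage) +
    covariates + N(0, sd).  ``targets`` maps variant names to dosage
    vectors; an effect naming an unknown target raises.
    """
    rng = np.random.default_rng(seed)
    cov = simulate_covariates(n_subjects, rng, n_pcs=n_pcs)
    cov_term = (_COVARIATE_EFFECTS["sex"] * cov["sex"].to_numpy()
                + _COVARIATE_EFFECTS["age_centered"]
                * (cov["age"].to_numpy() - cov["age"].mean())
                + _COVARIATE_EFFECTS["PC1"] * cov["PC1"].to_numpy())
    table = cov.copy()
    table.insert(0, "sample", sample_ids or
                 [f"S{i:06d}" for i in range(n_subjects)])

    by_trait: dict[str, list[EffectSpec]] = {}
    for e in effects:
        if e.target is not None and e.target not in targets:
            raise KeyError(f"effect target {e.target!r} not resolvable")
        by_trait.setdefault(e.trait, []).append(e)

    for trait, specs in by_trait.items():
        ttype = specs[0].trait_type
        genetic = np.zeros(n_subjects)
        for e in specs:
            if e.target is not None and e.effect != 0.0:
                d = np.nan_to_num(targets[e.target])
                genetic = genetic + e.effect * d
        if ttype == "binary":
            prevalence = specs[0].prevalence
            lp = genetic + cov_term
            lo, hi = -30.0, 30.0
            for _ in range(80):  # bisect intercept to hit the prevalence
                mid = 0.5 * (lo + hi)
                if np.mean(1 / (1 + np.exp(-(mid + lp)))) < prevalence:
                    lo = mid
                else:
                    hi = mid
            prob = 1 / (1 + np.exp(-(0.5 * (lo + hi) + lp)))
            table[trait] = (rng.random(n_subjects) < prob).astype(float)
        else:
            table[trait] = (genetic + cov_term
                            + rng.normal(0, specs[0].sd, n_subjects))
    return table


def make_aa_table(pool: ReferencePool, seq_len: int = 25, seed: int = 0
                  ) -> AminoAcidTable:
    """Assign each pool allele a residue string with family structure.

    Per gene: a shared base sequence; one family-determined position (so
    2-digit relatives share residues); one strictly biallelic position;
    and one position with a distinct residue per allele, giving >= 3
    residues whenever the gene has >= 3 alleles (omnibus df = n - 1).
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for gene in pool.genes:
        alleles = pool.gene_alleles(gene)
        if len(alleles) < 2:
            raise ValueError(f"gene {gene} has < 2 alleles")
        base = rng.choice(list(_RESIDUES), size=seq_len)
        p_family, p_bi, p_multi = 2, 5, 8
        for k, allele in enumerate(alleles):
            seq = base.copy()
            family = int(allele.split("*")[1].split(":")[0])
            seq[p_family] = _RESIDUES[family % len(_RESIDUES)]
            seq[p_bi] = _RESIDUES[family % 2]
            seq[p_multi] = _RESIDUES[k % len(_RESIDUES)]
            sequences[allele] = "".join(seq)
    return AminoAcidTable(sequences=sequences, offset=1)


# ---------------------------------------------------------------------------
# presets


def easy_preset(seed: int = 0) -> dict:
    """Strong-LD benchmark: 2 genes x 4 alleles, tagging 0.95."""
    return dict(n_haplotypes=500, n_snps=40, alleles_per_gene=4,
                tagging_strength=0.95, seed=seed, genes=("HLA-A", "HLA-B"))


def hard_preset(seed: int = 0) -> dict:
    """Weaker LD and more alleles: 3 genes x 6 alleles, tagging 0.8."""
    return dict(n_haplotypes=800, n_snps=60, alleles_per_gene=6,
                tagging_strength=0.8, seed=seed,
                genes=("HLA-A", "HLA-C", "HLA-B"))
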