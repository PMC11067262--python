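"""Genotype I/O and pre-analysis quality control.

Reads VCF (via cyvcf2) and PLINK bed/bim/fam into an additive dosage
matrix, applies the standard pre-association variant and sample filters
(call rate, MAF, Hardy-Weinberg, heterozygosity outliers, identity-by-
descent), and extracts the MHC region.

Coordinates are 1-based and region boundaries are inclusive at both ends.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: chromosome-6 MHC boundaries on GRCh38, inclusive (bp)
MHC_REGION = ("6", 28_510_120, 33_480_577)


@dataclass
class Region:
    """A 1-based, fully inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @classmethod
    def mhc(cls) -> "Region":
        return cls(*MHC_REGION)


@dataclass
class QCThresholds:
    """Variant/sample exclusion thresholds.

    Defaults are the conventional post-imputation filters: variant call
    rate >= 0.98, MAF >= 0.05, HWE exact p >= 1e-6; sample call rate
    >= 0.98, heterozygosity within mean +/- 3 SD, pairwise PI_HAT <= 0.1875.
    """

    variant_call_rate_min: float = 0.98
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    sample_call_rate_min: float = 0.98
    het_sd: float = 3.0
    ibd_max: float = 0.1875

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "maf_min", "hwe_p_min",
                     "sample_call_rate_min", "ibd_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.het_sd <= 0:
            raise ValueError("het_sd must be > 0")


@dataclass
class GenotypeMatrix:
    """Subjects x variants additive dosage matrix.

    ``dosage[i, j]`` counts ALT alleles (0/1/2) for sample i at variant j;
    missing genotypes are NaN.  ``variants`` has columns
    chrom, pos, id, ref, alt with ``pos`` 1-based.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})")
        required = {"chrom", "pos", "id", "ref", "alt"}
        if not required.issubset(self.variants.columns):
            raise ValueError(f"variant table missing {required - set(self.variants.columns)}")
        if len(self.variants):
            if (self.variants["ref"] == self.variants["alt"]).any():
                raise ValueError("ref == alt for some variant")
            for _, grp in self.variants.groupby("chrom", sort=False):
                if (np.diff(grp["pos"].to_numpy()) < 0).any():
                    raise ValueError("positions decrease within a chromosome")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosage=self.dosage[np.ix_(si, vi)].copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path: str, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (biallelic rows) or a PLINK bed prefix."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at line {k + 1} ({v.CHROM}:{v.POS}): "
                "split multiallelic sites before reading")
        rows.append((str(v.CHROM).removeprefix("chr"), v.POS,
                     v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
        gt = v.gt_types.astype(float)  # 0/1/2 alt count, 3 = missing
        gt[gt == 3] = np.nan
        dosages.append(gt)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosage = (np.asarray(dosages).T if dosages
              else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_genotypes(gm: GenotypeMatrix, path: str, format: str = "vcf") -> None:
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "plink":
        _write_plink(gm, path)
    else:
        raise ValueError(f"unknown format {format!r}")


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, var in gm.variants.iterrows():
            gts = [_GT_CODE.get(d, "./.") for d in gm.dosage[:, j]]
            fh.write(f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# PLINK bed 2-bit codes, SNP-major, a1 = ALT: 00 hom-a1, 10 het, 11 hom-a2,
# 01 missing.  Dosage counts a1 (= ALT) copies.
_BED_TO_DOSAGE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}
_DOSAGE_TO_BED = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _read_plink(prefix: str) -> GenotypeMatrix:
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != b"\x6c\x1b\x01":
            raise ValueError(f"{prefix}.bed: bad magic (not SNP-major PLINK bed)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if len(data) != bytes_per_snp * m:
        raise ValueError(f"{prefix}.bed: truncated ({len(data)} bytes, "
                         f"expected {bytes_per_snp * m})")
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    block = data.reshape(m, bytes_per_snp)
    for shift in range(4):
        codes[:, shift::4] = (block >> (2 * shift)) & 0b11
    lut = np.full(4, np.nan)
    for c, d in _BED_TO_DOSAGE.items():
        lut[c] = d
    dosage = lut[codes[:, :n]].T
    variants = pd.DataFrame({
        "chrom": bim["chrom"], "pos": bim["pos"], "id": bim["id"],
        "ref": bim["a2"], "alt": bim["a1"],
    })
    return GenotypeMatrix(samples=list(fam["iid"]), variants=variants, dosage=dosage)


def _write_plink(gm: GenotypeMatrix, prefix: str) -> None:
    with open(f"{prefix}.fam", "w") as fh:
        for s in gm.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for _, v in gm.variants.iterrows():
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt}\t{v.ref}\n")
    n = gm.n_samples
    bytes_per_snp = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(struct.pack("3B", 0x6C, 0x1B, 0x01))
        for j in range(gm.n_variants):
            codes = np.full(bytes_per_snp * 4, 0b01, dtype=np.uint8)
            for i, d in enumerate(gm.dosage[:, j]):
                codes[i] = _DOSAGE_TO_BED.get(d, 0b01)
            packed = np.zeros(bytes_per_snp, dtype=np.uint8)
            for shift in range(4):
                packed |= codes[shift::4] << (2 * shift)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value from genotype counts.

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the conditional probabilities that do not exceed the
    observed one (plain exact test, no mid-p).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | n, allele counts) up to a shared constant
    logp = (gammaln(n + 1)
            - gammaln((n_a - hets) / 2 + 1)
            - gammaln(hets + 1)
            - gammaln(n - (n_a + hets) / 2 + 1)
            + hets * np.log(2.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het]
    if len(p_obs) == 0:  # het count has wrong parity for the allele count
        raise ValueError("genotype counts inconsistent with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# per-variant / per-sample metrics and QC


def variant_metrics(gm: GenotypeMatrix) -> pd.DataFrame:
    """Call rate, MAF and HWE exact p per variant (missing excluded)."""
    d = gm.dosage
    n_obs = np.sum(~np.isnan(d), axis=0)
    call_rate = n_obs / max(gm.n_samples, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_af = np.nansum(d, axis=0) / np.maximum(2 * n_obs, 1)
    maf = np.minimum(alt_af, 1 - alt_af)
    hwe_p = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            continue
        hwe_p[j] = hwe_exact_test(int((obs == 0).sum()), int((obs == 1).sum()),
                                  int((obs == 2).sum()))
    return pd.DataFrame({
        "variant_id": gm.variants["id"].to_numpy(),
        "call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
    })


def variant_qc(gm: GenotypeMatrix, thr: QCThresholds | None = None
               ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing call-rate, MAF or HWE thresholds.

    Returns the filtered matrix and a per-variant report with metrics,
    pass/fail status and comma-joined fail reasons.
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    thr = thr or QCThresholds()
    rep = variant_metrics(gm)
    reasons = []
    for _, r in rep.iterrows():
        why = []
        if r.call_rate < thr.variant_call_rate_min:
            why.append("call_rate")
        if r.maf < thr.maf_min:
            why.append("maf")
        if r.hwe_p < thr.hwe_p_min:
            why.append("hwe")
        reasons.append(",".join(why))
    rep["reason"] = reasons
    rep["status"] = np.where(rep["reason"] == "", "pass", "fail")
    keep = np.flatnonzero(rep["status"].to_numpy() == "pass")
    return gm.subset(variant_idx=keep), rep


def ibd_pi_hat(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise method-of-moments PI_HAT (symmetric, zero diagonal).

    The PLINK-style estimator: observed IBS0/1/2 counts per pair are
    compared with their expectations under IBD state 0/1/2 given observed
    allele frequencies, solving for P(IBD=z) and PI_HAT = P(1)/2 + P(2).
    """
    d = gm.dosage
    miss = np.isnan(d)
    n_obs = (~miss).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(d, axis=0) / np.maximum(2 * n_obs, 1)  # alt freq
    informative = (p > 0) & (p < 1)
    p = p[informative]
    q = 1 - p
    d = np.where(miss, -9.0, d)[:, informative]
    n = gm.n_samples
    # indicator matrices per genotype class
    g0, g1, g2 = (d == 0).astype(float), (d == 1).astype(float), (d == 2).astype(float)
    valid = (d >= 0).astype(float)
    n_pair = valid @ valid.T
    # IBS2: same genotype; IBS0: opposite homozygotes
    ibs2 = g0 @ g0.T + g1 @ g1.T + g2 @ g2.T
    ibs0 = g0 @ g2.T + g2 @ g0.T
    ibs1 = n_pair - ibs2 - ibs0
    # expectations summed over variants (no small-sample correction)
    e00 = np.sum(2 * p**2 * q**2)
    e10 = np.sum(4 * p**3 * q + 4 * p * q**3)
    e20 = np.sum(p**4 + q**4 + 4 * p**2 * q**2)
    e11 = np.sum(2 * p**2 * q + 2 * p * q**2)
    e21 = np.sum(p**3 + q**3 + p**2 * q + p * q**2)
    m = len(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = n_pair / m  # fraction of informative variants observed per pair
        z0 = ibs0 / (e00 * scale)
        z1 = (ibs1 - z0 * e10 * scale) / (e11 * scale)
        z2 = (ibs2 - z0 * e20 * scale - z1 * e21 * scale) / n_pair
    z0, z1, z2 = (np.clip(z, 0, 1) for z in (z0, z1, z2))
    tot = z0 + z1 + z2
    tot[tot == 0] = 1.0
    pi_hat = (0.5 * z1 + z2) / tot
    np.fill_diagonal(pi_hat, 0.0)
    return np.nan_to_num(pi_hat)


def sample_qc(gm: GenotypeMatrix, thr: QCThresholds | None = None,
              reported_sex: dict[str, int] | None = None,
              inferred_sex: dict[str, int] | None = None,
              min_ibd_variants: int = 100,
              ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples failing call-rate, heterozygosity, IBD or sex checks.

    For each IBD pair above ``thr.ibd_max`` both members are flagged and the
    one with the lower call rate is dropped (tie: the lexicographically
    larger ID).  The heterozygosity filter needs >= 3 samples; the
    method-of-moments IBD estimate needs many quasi-independent variants,
    so the IBD filter is skipped (with a warning) below
    ``min_ibd_variants``; the sex check runs only when both reported and
    inferred sex are provided.
    """
    if gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    thr = thr or QCThresholds()
    d = gm.dosage
    n_obs = (~np.isnan(d)).sum(axis=1)
    call_rate = n_obs / max(gm.n_variants, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        het_rate = np.nansum(d == 1, axis=1) / np.maximum(n_obs, 1)
    reasons: list[list[str]] = [[] for _ in gm.samples]
    for i in np.flatnonzero(call_rate < thr.sample_call_rate_min):
        reasons[i].append("call_rate")
    if gm.n_samples >= 3:
        mu, sd = het_rate.mean(), het_rate.std(ddof=1)
        if sd > 0:
            out = np.abs(het_rate - mu) > thr.het_sd * sd
            for i in np.flatnonzero(out):
                reasons[i].append("heterozygosity")
    else:
        warnings.warn("fewer than 3 samples: heterozygosity filter skipped")
    if gm.n_variants >= min_ibd_variants:
        pi = ibd_pi_hat(gm)
    else:
        warnings.warn(f"fewer than {min_ibd_variants} variants: "
                      "IBD filter skipped (estimator unstable)")
        pi = np.zeros((gm.n_samples, gm.n_samples))
    ii, jj = np.nonzero(np.triu(pi > thr.ibd_max, k=1))
    for i, j in zip(ii, jj):
        # drop the lower-call-rate member; tie -> lexicographically larger ID
        if call_rate[i] < call_rate[j]:
            drop = i
        elif call_rate[j] < call_rate[i]:
            drop = j
        else:
            drop = i if gm.samples[i] > gm.samples[j] else j
        if "ibd" not in reasons[drop]:
            reasons[drop].append("ibd")
    if reported_sex is not None and inferred_sex is not None:
        for i, s in enumerate(gm.samples):
            if s in reported_sex and s in inferred_sex and \
                    reported_sex[s] != inferred_sex[s]:
                reasons[i].append("sex_mismatch")
    rep = pd.DataFrame({
        "sample_id": gm.samples,
        "call_rate": call_rate,
        "het_rate": het_rate,
        "max_pi_hat": pi.max(axis=1) if gm.n_samples > 1 else 0.0,
        "reason": [",".join(r) for r in reasons],
    })
    rep["status"] = np.where(rep["reason"] == "", "pass", "fail")
    keep = np.flatnonzero(rep["status"].to_numpy() == "pass")
    return gm.subset(sample_idx=keep), rep


def extract_region(gm: GenotypeMatrix, region: Region) -> GenotypeMatrix:
    """Keep variants with region.start <= pos <= region.end on region.chrom."""
    chrom = gm.variants["chrom"].astype(str).str.removeprefix("chr")
    keep = np.flatnonzero(
        (chrom == str(region.chrom).removeprefix("chr"))
        & (gm.variants["pos"] >= region.start)
        & (gm.variants["pos"] <= region.end))
    return gm.subset(variant_idx=keep)
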