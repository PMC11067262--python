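"""HLA nomenclature, amino-acid translation and the PheWAS variant catalogue.

The catalogue unifies four classes of biallelic test variants — SNVs,
indels, HLA alleles (as 0/1/2 allele-count dosages) and amino-acid residue
presence/absence variants — plus multiallelic amino-acid positions tested
with the omnibus likelihood-ratio test.  Residue variants are named
``GENE-<residue><position>`` (e.g. ``HLA-B-Q94``) and positions
``GENE pos <position>`` (e.g. ``HLA-B pos 138``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASSICAL_GENES = ("HLA-A", "HLA-B", "HLA-C", "HLA-DRB1",
                   "HLA-DPA1", "HLA-DPB1", "HLA-DQA1", "HLA-DQB1")

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([A-Z]+\d*)\*(\d+)(?::(\d+))?(?::(\d+))?[A-Z]?$")


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A classical HLA allele at 2-, 4- or 6-digit resolution."""

    gene: str
    fields: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 3 or any(f < 0 for f in self.fields):
            raise ValueError(f"invalid allele fields {self.fields}")

    @property
    def resolution(self) -> int:
        return 2 * len(self.fields)

    def __str__(self) -> str:
        short = self.gene.removeprefix("HLA-")
        return f"{short}*" + ":".join(f"{f:02d}" for f in self.fields)


def parse_allele(text: str) -> HLAAllele:
    """Parse colon-delimited nomenclature like ``B*58:01`` or ``HLA-B*27:04:01``.

    A trailing expression-suffix letter (N/L/S/Q...) is stripped.
    """
    m = _ALLELE_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed HLA allele: {text!r}")
    gene = f"HLA-{m.group(1)}"
    fields = tuple(int(g) for g in m.groups()[1:] if g is not None)
    return HLAAllele(gene=gene, fields=fields)


def truncate(allele: HLAAllele, resolution: int) -> HLAAllele:
    """Reduce an allele to 2-, 4- or 6-digit resolution by dropping fields."""
    if resolution not in (2, 4, 6):
        raise ValueError(f"resolution must be 2, 4 or 6, got {resolution}")
    if resolution > allele.resolution:
        raise ValueError(
            f"cannot raise {allele} (resolution {allele.resolution}) "
            f"to {resolution} digits")
    return HLAAllele(gene=allele.gene, fields=allele.fields[: resolution // 2])


# ---------------------------------------------------------------------------
# amino-acid table


@dataclass
class AminoAcidTable:
    """Protein sequences keyed by 4-digit allele text (e.g. ``B*58:01``).

    ``offset`` is the protein coordinate of the first residue.  Sequences
    for alleles of the same gene must have equal length; residues are
    uppercase letters or '-' for an indel/absent residue.
    """

    sequences: dict[str, str]
    offset: int = 1

    def __post_init__(self) -> None:
        lengths: dict[str, int] = {}
        for allele, seq in self.sequences.items():
            gene = parse_allele(allele).gene
            if not re.fullmatch(r"[A-Z\-]+", seq):
                raise ValueError(f"invalid residues in sequence for {allele}")
            if lengths.setdefault(gene, len(seq)) != len(seq):
                raise ValueError(f"unequal sequence lengths for {gene}")

    def genes(self) -> list[str]:
        return sorted({parse_allele(a).gene for a in self.sequences})


def write_aa_table(table: AminoAcidTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("allele\toffset\tsequence\n")
        for allele, seq in table.sequences.items():
            fh.write(f"{allele}\t{table.offset}\t{seq}\n")


def read_aa_table(path: str) -> AminoAcidTable:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "sequence": str})
    offsets = df["offset"].unique()
    return AminoAcidTable(
        sequences=dict(zip(df["allele"], df["sequence"])),
        offset=int(offsets[0]))


# ---------------------------------------------------------------------------
# typing / call tables


def write_typing_table(typing: pd.DataFrame, path: str) -> None:
    typing.to_csv(path, sep="\t", index=False)


def read_typing_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "gene", "allele1", "allele2"):
        if col not in df.columns:
            raise ValueError(f"typing table missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# catalogue


@dataclass
class MultiallelicPosition:
    """One amino-acid position with >= 2 observed residues."""

    gene: str
    position: int
    residues: list[str]
    dosage: np.ndarray  # residues x subjects, NaN for uncalled subjects

    @property
    def id(self) -> str:
        return f"{self.gene} pos {self.position}"

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class VariantCatalogue:
    """Unified biallelic test variants plus multiallelic amino-acid positions.

    ``biallelic`` columns: id, source in {snv, indel, hla_allele,
    aa_residue}, gene ('-' when unassigned); ``dosage`` is subjects x
    biallelic variants.
    """

    samples: list[str]
    biallelic: pd.DataFrame
    dosage: np.ndarray = field(repr=False)
    multiallelic: list[MultiallelicPosition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.biallelic)):
            raise ValueError("dosage shape mismatch")
        bad = set(self.biallelic["source"]) - {"snv", "indel", "hla_allele",
                                               "aa_residue"}
        if bad:
            raise ValueError(f"unknown variant sources {bad}")

    def counts(self) -> dict[str, int]:
        c = self.biallelic["source"].value_counts().to_dict()
        return {
            "snv": c.get("snv", 0),
            "indel": c.get("indel", 0),
            "hla_allele": c.get("hla_allele", 0),
            "aa_residue": c.get("aa_residue", 0),
            "multiallelic_position": len(self.multiallelic),
        }

    def total(self) -> int:
        return catalogue_total(self.counts())

    def dosage_of(self, variant_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.biallelic["id"].to_numpy() == variant_id)
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in catalogue")
        return self.dosage[:, idx[0]]


def catalogue_total(counts: dict[str, int]) -> int:
    """Catalogue accounting rule: biallelic classes plus multiallelic positions."""
    return (counts["snv"] + counts["indel"] + counts["hla_allele"]
            + counts["aa_residue"] + counts["multiallelic_position"])


def allele_dosages(calls: pd.DataFrame, samples: list[str]
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """HLA-allele dosage variants from a per-gene call table.

    ``calls`` columns: sample, gene, allele1, allele2 and optional boolean
    ``called``.  Uncalled subjects get missing dosage for every allele of
    that gene; dosages of a called subject sum to 2 within a gene.
    """
    calls = calls.copy()
    if "called" not in calls.columns:
        calls["called"] = True
    sample_idx = {s: i for i, s in enumerate(samples)}
    meta_rows, columns = [], []
    for gene, grp in calls.groupby("gene", sort=True):
        alleles = sorted(set(grp.loc[grp["called"], "allele1"])
                         | set(grp.loc[grp["called"], "allele2"]))
        a_idx = {a: k for k, a in enumerate(alleles)}
        dos = np.full((len(samples), len(alleles)), np.nan)
        called_rows = grp[grp["called"]]
        rows = [sample_idx[s] for s in called_rows["sample"]]
        dos[rows, :] = 0.0
        for i, a1, a2 in zip(rows, called_rows["allele1"], called_rows["allele2"]):
            dos[i, a_idx[a1]] += 1
            dos[i, a_idx[a2]] += 1
        for a in alleles:
            meta_rows.append({"id": f"HLA-{a}" if not a.startswith("HLA-") else a,
                              "source": "hla_allele", "gene": gene})
        columns.append(dos)
    meta = pd.DataFrame(meta_rows, columns=["id", "source", "gene"])
    dosage = np.hstack(columns) if columns else np.empty((len(samples), 0))
    return meta, dosage


def translate_amino_acids(calls: pd.DataFrame, table: AminoAcidTable,
                          samples: list[str]
                          ) -> tuple[list[MultiallelicPosition], pd.DataFrame,
                                     np.ndarray]:
    """Translate called alleles to residues and enumerate polymorphisms.

    Returns (multiallelic positions, biallelic residue variant metadata,
    residue dosage matrix).  Positions with a single observed residue are
    dropped.  Alleles absent from the table make the subject missing at
    that gene's positions (with a warning).  Alleles beyond 4-digit
    resolution are truncated to protein level first.
    """
    calls = calls.copy()
    if "called" not in calls.columns:
        calls["called"] = True
    sample_idx = {s: i for i, s in enumerate(samples)}
    positions: list[MultiallelicPosition] = []
    res_meta_rows, res_cols = [], []
    missing_alleles: set[str] = set()

    def to_protein_key(name: str) -> str | None:
        allele = parse_allele(name)
        if allele.resolution > 4:
            allele = truncate(allele, 4)
        key = str(allele)
        if key not in table.sequences:
            missing_alleles.add(name)
            return None
        return key

    for gene, grp in calls.groupby("gene", sort=True):
        gene_alleles = [a for a in table.sequences
                        if parse_allele(a).gene == gene]
        if not gene_alleles:
            continue
        seq_len = len(table.sequences[gene_alleles[0]])
        # per subject, the two protein sequences (None = missing)
        pairs: dict[int, tuple[str, str] | None] = {}
        for _, row in grp.iterrows():
            i = sample_idx[row["sample"]]
            if not row["called"]:
                pairs[i] = None
                continue
            k1, k2 = to_protein_key(row["allele1"]), to_protein_key(row["allele2"])
            pairs[i] = None if (k1 is None or k2 is None) else (k1, k2)
        for p in range(seq_len):
            observed: dict[str, None] = {}
            for pr in pairs.values():
                if pr is not None:
                    observed.setdefault(table.sequences[pr[0]][p])
                    observed.setdefault(table.sequences[pr[1]][p])
            residues = sorted(observed)
            if len(residues) < 2:
                continue
            r_idx = {r: k for k, r in enumerate(residues)}
            dos = np.full((len(residues), len(samples)), np.nan)
            for i, pr in pairs.items():
                if pr is None:
                    continue
                dos[:, i] = 0.0
                dos[r_idx[table.sequences[pr[0]][p]], i] += 1
                dos[r_idx[table.sequences[pr[1]][p]], i] += 1
            coord = table.offset + p
            positions.append(MultiallelicPosition(
                gene=gene, position=coord, residues=residues, dosage=dos))
            for r in residues:
                res_meta_rows.append({"id": f"{gene}-{r}{coord}",
                                      "source": "aa_residue", "gene": gene})
                res_cols.append(dos[r_idx[r]])
    if missing_alleles:
        warnings.warn("alleles absent from amino-acid table treated as "
                      f"missing: {sorted(missing_alleles)}")
    res_meta = pd.DataFrame(res_meta_rows, columns=["id", "source", "gene"])
    res_dosage = (np.column_stack(res_cols) if res_cols
                  else np.empty((len(samples), 0)))
    return positions, res_meta, res_dosage


def build_catalogue(samples: list[str], snv_gm=None, calls: pd.DataFrame | None = None,
                    aa_table: AminoAcidTable | None = None) -> VariantCatalogue:
    """Assemble a catalogue from region SNVs/indels, HLA calls and an AA table."""
    metas, mats = [], []
    if snv_gm is not None:
        is_indel = np.array([len(r) != 1 or len(a) != 1
                             for r, a in zip(snv_gm.variants["ref"],
                                             snv_gm.variants["alt"])])
        metas.append(pd.DataFrame({
            "id": snv_gm.variants["id"],
            "source": np.where(is_indel, "indel", "snv"),
            "gene": "-",
        }))
        mats.append(snv_gm.dosage)
    multiallelic: list[MultiallelicPosition] = []
    if calls is not None:
        a_meta, a_dos = allele_dosages(calls, samples)
        metas.append(a_meta)
        mats.append(a_dos)
        if aa_table is not None:
            multiallelic, r_meta, r_dos = translate_amino_acids(
                calls, aa_table, samples)
            metas.append(r_meta)
            mats.append(r_dos)
    biallelic = (pd.concat(metas, ignore_index=True) if metas
                 else pd.DataFrame(columns=["id", "source", "gene"]))
    dosage = np.hstack(mats) if mats else np.empty((len(samples), 0))
    return VariantCatalogue(samples=samples, biallelic=biallelic,
                            dosage=dosage, multiallelic=multiallelic)


def post_imputation_qc(catalogue: VariantCatalogue,
                       missing_max: float = 0.05,
                       maf_min: float = 0.01) -> VariantCatalogue:
    """Post-imputation filters on the HLA-derived catalogue entries.

    HLA alleles and biallelic residue variants: drop if missing rate >
    ``missing_max`` or MAF < ``maf_min``.  Multiallelic positions: missing
    rate only.  SNVs and indels pass through untouched (QCed upstream).
    """
    n = len(catalogue.samples)
    keep = np.ones(len(catalogue.biallelic), dtype=bool)
    src = catalogue.biallelic["source"].to_numpy()
    for j in np.flatnonzero(np.isin(src, ("hla_allele", "aa_residue"))):
        col = catalogue.dosage[:, j]
        miss = np.isnan(col).mean()
        obs = col[~np.isnan(col)]
        af = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
        maf = min(af, 1 - af)
        if miss > missing_max or maf < maf_min:
            keep[j] = False
    multi = [pos for pos in catalogue.multiallelic
             if np.isnan(pos.dosage[0]).mean() <= missing_max]
    return VariantCatalogue(
        samples=catalogue.samples,
        biallelic=catalogue.biallelic[keep].reset_index(drop=True),
        dosage=catalogue.dosage[:, keep],
        multiallelic=multi)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete subjects.

    NaN when either vector has zero variance on the complete subset.
    """
    a, b = np.asarray(dosage_a, float), np.asarray(dosage_b, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete subjects")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov * cov / (va * vb))


def assign_to_gene(catalogue: VariantCatalogue,
                   r2_threshold: float = 0.7) -> VariantCatalogue:
    """Tag SNVs/indels with every gene whose HLA allele or residue variant
    is in LD at r^2 >= threshold (boundary inclusive); '-' when none."""
    bi = catalogue.biallelic.copy()
    src = bi["source"].to_numpy()
    hla_idx = np.flatnonzero(np.isin(src, ("hla_allele", "aa_residue")))
    snp_idx = np.flatnonzero(np.isin(src, ("snv", "indel")))
    genes = bi["gene"].to_numpy(dtype=object).copy()
    for j in snp_idx:
        tagged = set()
        for k in hla_idx:
            r2 = ld_r2(catalogue.dosage[:, j], catalogue.dosage[:, k])
            if not np.isnan(r2) and r2 >= r2_threshold:
                tagged.add(bi["gene"].iloc[k])
        genes[j] = ",".join(sorted(tagged)) if tagged else "-"
    bi["gene"] = genes
    return replace(catalogue, biallelic=bi)
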