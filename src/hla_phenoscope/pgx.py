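"""Carrier screening for adverse-drug-reaction-associated HLA alleles.

Summarizes, from imputed calls, the carrier count, carrier percentage and
allele frequency of each allele on a curated ADR list (shipped as package
data), together with the Hardy-Weinberg expected carrier fraction
1 - (1 - p)^2 as a consistency diagnostic.  A carrier is a subject with
at least one copy; the denominator is the subjects called at the
allele's gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .variant_encoding import parse_allele


@dataclass
class ADRAlleleEntry:
    allele: str
    drugs: str = ""
    reaction: str = ""
    population: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        parse_allele(self.allele)  # raises on malformed nomenclature


def load_adr_alleles(path: str | None = None) -> list[ADRAlleleEntry]:
    """The bundled ADR-allele list (or a user TSV with the same columns)."""
    if path is None:
        source = resources.files("hla_phenoscope.data") / "adr_alleles.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    entries = []
    for _, r in df.iterrows():
        try:
            entries.append(ADRAlleleEntry(
                allele=r["allele"], drugs=r.get("drugs", ""),
                reaction=r.get("reaction", ""),
                population=r.get("population", ""),
                citation=r.get("citation", "")))
        except ValueError as e:
            raise ValueError(f"unparseable ADR allele {r['allele']!r}") from e
    return entries


def hwe_expected_carriers(allele_frequency: float) -> float:
    """Expected carrier fraction under HWE: 1 - (1 - p)^2."""
    p = float(allele_frequency)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    return 1.0 - (1.0 - p) ** 2


def carrier_report(calls: pd.DataFrame,
                   adr_list: list[ADRAlleleEntry] | None = None
                   ) -> pd.DataFrame:
    """Carrier counts and frequencies of ADR alleles from imputed calls.

    ``calls`` columns: sample, gene, allele1, allele2 and optional boolean
    ``called`` (uncalled subjects leave the denominator).  Alleles absent
    from the cohort are reported with count 0.  A homozygote counts once
    as a carrier but contributes two copies to the allele frequency.
    """
    if adr_list is None:
        adr_list = load_adr_alleles()
    calls = calls.copy()
    if "called" not in calls.columns:
        calls["called"] = True
    calls = calls[calls["called"]]
    # canonicalize call alleles through the parser for robust matching
    by_gene: dict[str, pd.DataFrame] = {
        g: grp for g, grp in calls.groupby("gene", sort=False)}
    rows = []
    for entry in adr_list:
        allele = parse_allele(entry.allele)
        gene = allele.gene
        key = str(allele)
        grp = by_gene.get(gene)
        if grp is None or len(grp) == 0:
            rows.append({
                "allele": f"HLA-{key}", "gene": gene, "carriers": 0,
                "cohort_size": 0, "carrier_pct": 0.0, "allele_frequency": 0.0,
                "hwe_expected_pct": 0.0, "drugs": entry.drugs,
                "reaction": entry.reaction, "population": entry.population,
            })
            continue
        a1 = grp["allele1"].map(lambda a: str(parse_allele(a)))
        a2 = grp["allele2"].map(lambda a: str(parse_allele(a)))
        copies = (a1 == key).astype(int) + (a2 == key).astype(int)
        n = len(grp)
        carriers = int((copies >= 1).sum())
        freq = float(copies.sum()) / (2 * n)
        rows.append({
            "allele": f"HLA-{key}", "gene": gene, "carriers": carriers,
            "cohort_size": n,
            "carrier_pct": round(100.0 * carriers / n, 2),
            "allele_frequency": round(freq, 4),
            "hwe_expected_pct": round(100.0 * hwe_expected_carriers(freq), 2),
            "drugs": entry.drugs, "reaction": entry.reaction,
            "population": entry.population,
        })
    return pd.DataFrame(rows)
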