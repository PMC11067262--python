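"""EM estimation of multilocus HLA haplotype frequencies from unphased typings.

The standard multilocus EM: the E-step distributes each subject's
probability mass across every haplotype-pair resolution of their
unordered genotypes, the M-step re-estimates haplotype frequencies, and
iteration stops when the log-likelihood gain falls below tolerance.
Genes are inserted progressively in the given order with pruning of
negligible haplotypes between insertions, so the haplotype space stays
restricted to combinations compatible with at least one subject.
Initialization is the product of marginal allele frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: five-gene order used for cross-population haplotype comparisons
FIVE_GENE_ORDER = ("HLA-A", "HLA-C", "HLA-B", "HLA-DRB1", "HLA-DQB1")
EIGHT_GENE_ORDER = ("HLA-A", "HLA-C", "HLA-B", "HLA-DRB1", "HLA-DQA1",
                    "HLA-DQB1", "HLA-DPA1", "HLA-DPB1")


@dataclass
class HaplotypeFrequencyTable:
    gene_order: list[str]
    frequencies: dict[tuple[str, ...], float]
    log_likelihood: float
    iterations: int
    n_subjects: int = 0

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-6:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("negative haplotype frequency")

    def as_frame(self) -> pd.DataFrame:
        rows = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame({
            "haplotype": ["-".join(h) for h, _ in rows],
            "frequency": [f for _, f in rows],
        })
        df["cumulative"] = df["frequency"].cumsum()
        return df


def _genotype_rows(typing: pd.DataFrame, genes: list[str]
                   ) -> tuple[list[list[tuple[str, str]]], int]:
    """Per-subject unordered allele pairs in gene order; subjects missing a
    gene are excluded with a warning."""
    by_sample: dict[str, dict[str, tuple[str, str]]] = {}
    called = typing
    if "called" in typing.columns:
        called = typing[typing["called"]]
    for _, r in called.iterrows():
        by_sample.setdefault(r["sample"], {})[r["gene"]] = (
            r["allele1"], r["allele2"])
    rows, dropped = [], 0
    for sample, genotypes in by_sample.items():
        if all(g in genotypes for g in genes):
            rows.append([genotypes[g] for g in genes])
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} subjects missing a requested gene excluded "
                      "from haplotype estimation")
    if not rows:
        raise ValueError("no subjects typed at all requested genes")
    return rows, dropped


def em_haplotype_frequencies(typing: pd.DataFrame, genes: list[str],
                             tol: float = 1e-8, max_iter: int = 1000,
                             insert_prune: float = 1e-7,
                             output_prune: float = 1e-6,
                             ) -> HaplotypeFrequencyTable:
    """Maximum-likelihood multilocus haplotype frequencies by EM.

    ``typing`` columns: sample, gene, allele1, allele2 (plus optional
    boolean ``called``; uncalled rows are ignored).  Genes are inserted
    progressively in ``genes`` order; haplotypes below ``insert_prune``
    are dropped between insertions and below ``output_prune`` at output.
    The log-likelihood is asserted non-decreasing at every EM iteration.
    """
    genes = list(genes)
    if len(genes) < 1:
        raise ValueError("need at least one gene")
    rows, _ = _genotype_rows(typing, genes)
    if len(rows) < 2:
        raise ValueError("need >= 2 subjects")
    n = len(rows)

    # state: haplotypes as tuples of allele names over inserted genes;
    # per subject, ordered pair expansions (indices into haplotype list)
    haps: list[tuple[str, ...]] = [()]
    hap_index = {(): 0}
    freq = np.array([1.0])
    r_subj = np.arange(n)
    r_h1 = np.zeros(n, dtype=np.int64)
    r_h2 = np.zeros(n, dtype=np.int64)
    total_iters = 0
    ll = -np.inf

    def run_em(max_it: int, tolerance: float) -> tuple[float, int]:
        nonlocal freq
        prev = -np.inf
        it = 0
        for it in range(1, max_it + 1):
            w = freq[r_h1] * freq[r_h2]
            denom = np.bincount(r_subj, weights=w, minlength=n)
            if (denom <= 0).any():
                w = np.where(denom[r_subj] <= 0, 1.0, w)
                denom = np.bincount(r_subj, weights=w, minlength=n)
            cur = float(np.log(denom).sum())
            if np.isfinite(prev) and cur < prev - 1e-9:
                raise AssertionError("EM log-likelihood decreased")
            post = w / denom[r_subj]
            new = (np.bincount(r_h1, weights=post, minlength=len(freq))
                   + np.bincount(r_h2, weights=post, minlength=len(freq))
                   ) / (2 * n)
            freq = new / new.sum()
            if np.isfinite(prev) and cur - prev < tolerance:
                prev = cur
                break
            prev = cur
        return prev, it

    for g, gene in enumerate(genes):
        # marginal allele frequencies for initialization
        pairs_g = [row[g] for row in rows]
        marg: dict[str, float] = {}
        for a1, a2 in pairs_g:
            marg[a1] = marg.get(a1, 0.0) + 1.0
            marg[a2] = marg.get(a2, 0.0) + 1.0
        for a in marg:
            marg[a] /= 2 * n
        new_haps: list[tuple[str, ...]] = []
        new_index: dict[tuple[str, ...], int] = {}
        new_freq: list[float] = []

        def hap_id(base: tuple[str, ...], allele: str) -> int:
            h = base + (allele,)
            if h not in new_index:
                new_index[h] = len(new_haps)
                new_haps.append(h)
                new_freq.append(freq[hap_index[base]] * marg[allele])
            return new_index[h]

        ns, n1, n2 = [], [], []
        for r in range(len(r_subj)):
            s = r_subj[r]
            a1, a2 = rows[s][g]
            b1, b2 = haps[r_h1[r]], haps[r_h2[r]]
            options = {(a1, a2)} | {(a2, a1)}
            for x1, x2 in options:
                ns.append(s)
                n1.append(hap_id(b1, x1))
                n2.append(hap_id(b2, x2))
        haps, hap_index = new_haps, new_index
        freq = np.asarray(new_freq)
        freq = freq / freq.sum()
        r_subj = np.asarray(ns)
        r_h1, r_h2 = np.asarray(n1), np.asarray(n2)
        is_last = g == len(genes) - 1
        ll, iters = run_em(max_iter, tol if is_last else max(tol, 1e-6))
        total_iters += iters
        prune = output_prune if is_last else insert_prune
        keep = freq >= prune
        # never orphan a subject: keep each subject's best expansion
        w = freq[r_h1] * freq[r_h2]
        best_rows = np.zeros(len(w), dtype=bool)
        order = np.lexsort((w, r_subj))
        last = np.ones(len(order), dtype=bool)
        last[:-1] = r_subj[order][1:] != r_subj[order][:-1]
        best_rows[order[last]] = True
        keep_row = (keep[r_h1] & keep[r_h2]) | best_rows
        used = np.union1d(r_h1[keep_row], r_h2[keep_row])
        remap = -np.ones(len(freq), dtype=np.int64)
        remap[used] = np.arange(len(used))
        r_subj = r_subj[keep_row]
        r_h1, r_h2 = remap[r_h1[keep_row]], remap[r_h2[keep_row]]
        haps = [haps[u] for u in used]
        hap_index = {h: i for i, h in enumerate(haps)}
        freq = freq[used]
        freq = freq / freq.sum()

    ll, iters = run_em(max_iter, tol)  # final polish after output pruning
    total_iters += iters
    keep = freq >= output_prune
    frequencies = {haps[i]: float(freq[i]) for i in np.flatnonzero(keep)}
    total = sum(frequencies.values())
    frequencies = {h: f / total for h, f in frequencies.items()}
    return HaplotypeFrequencyTable(gene_order=genes, frequencies=frequencies,
                                   log_likelihood=ll, iterations=total_iters,
                                   n_subjects=n)


def top_haplotypes(table: HaplotypeFrequencyTable, k: int) -> pd.DataFrame:
    """Top-k haplotypes by frequency (ties broken lexicographically),
    formatted as '-'-joined allele strings with cumulative frequencies."""
    df = table.as_frame()
    return df.head(min(k, len(df))).reset_index(drop=True)
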