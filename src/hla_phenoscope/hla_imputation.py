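"""Attribute-bagging HLA imputation from SNP genotypes.

A reference panel for one gene/resolution is an ensemble of classifiers
(default 100).  Each classifier is trained on a bootstrap sample of the
typed subjects: a SNP subset is grown greedily from the gene's flanking
window (candidates drawn at random each step, attribute bagging), accepting
a SNP only when it raises out-of-bag allele-prediction accuracy, and the
joint frequencies of (SNP-subset haplotype pattern, HLA allele) are
estimated by EM over the unphased data.  Imputation averages the
allele-pair posterior across classifiers; a genotype is called when the
best pair's posterior reaches the call threshold (default 0.5).

Accuracy is scored per allele: each subject contributes two alleles,
matched as unordered pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix
from .variant_encoding import parse_allele, truncate

MODEL_FORMAT_VERSION = 1

try:  # gene anchors shared with the synthetic generator
    from .synthetic_data import GENE_ANCHORS
except ImportError:  # pragma: no cover
    GENE_ANCHORS = {}


# ---------------------------------------------------------------------------
# EM over unphased (SNP genotype, allele pair) data
#
# State holds ordered-pair phase expansions: row r says subject r_subj is
# haplotypes (r_h1, r_h2), where a haplotype is (allele code, SNP-pattern
# bitmask over the selected SNPs).  Ordered pairs make the likelihood
# bookkeeping trivial: P(subject) = sum over its rows of f[h1] * f[h2].


class _EMState:
    def __init__(self, allele_pairs: np.ndarray, n_alleles: int):
        # allele_pairs: (n, 2) int codes per bootstrap subject
        n = len(allele_pairs)
        self.n_subjects = n
        self.k = 0  # number of selected SNPs
        a1, a2 = allele_pairs[:, 0], allele_pairs[:, 1]
        het = a1 != a2
        subj = np.concatenate([np.arange(n), np.arange(n)[het]])
        h1 = np.concatenate([a1, a2[het]])
        h2 = np.concatenate([a2, a1[het]])
        self.hap_allele = np.arange(n_alleles)
        self.hap_bits = np.zeros(n_alleles, dtype=np.int64)
        self.r_subj, self.r_h1, self.r_h2 = subj, h1, h2
        counts = np.bincount(np.concatenate([a1, a2]), minlength=n_alleles)
        self.freq = counts / counts.sum()
        self.loglik = -np.inf

    def copy(self) -> "_EMState":
        st = object.__new__(_EMState)
        st.n_subjects, st.k = self.n_subjects, self.k
        for name in ("hap_allele", "hap_bits", "r_subj", "r_h1", "r_h2", "freq"):
            setattr(st, name, getattr(self, name).copy())
        st.loglik = self.loglik
        return st

    def extend(self, dosage: np.ndarray) -> None:
        """Add one SNP; each row splits per phase-consistent bit assignment."""
        d = dosage[self.r_subj]
        pieces = []
        for sel, bits in ((d == 0, [(0, 0)]), (d == 2, [(1, 1)]),
                          (d == 1, [(0, 1), (1, 0)]),
                          (np.isnan(d), [(0, 0), (0, 1), (1, 0), (1, 1)])):
            idx = np.flatnonzero(sel)
            for b1, b2 in bits:
                pieces.append((idx, b1, b2))
        subj = np.concatenate([self.r_subj[i] for i, _, _ in pieces])
        key1 = np.concatenate([self.r_h1[i] * 2 + b1 for i, b1, _ in pieces])
        key2 = np.concatenate([self.r_h2[i] * 2 + b2 for i, _, b2 in pieces])
        uniq, inv = np.unique(np.concatenate([key1, key2]), return_inverse=True)
        old = uniq >> 1
        bit = uniq & 1
        new_bits = self.hap_bits[old] | (bit.astype(np.int64) << self.k)
        new_freq = self.freq[old] * np.where(
            bit == 1, 0.5, 0.5)  # split mass evenly between branches
        self.hap_allele = self.hap_allele[old]
        self.hap_bits = new_bits
        self.freq = new_freq / new_freq.sum()
        m = len(key1)
        self.r_subj, self.r_h1, self.r_h2 = subj, inv[:m], inv[m:]
        self.k += 1
        self.loglik = -np.inf

    def em(self, max_iter: int = 500, tol: float = 1e-7) -> None:
        """Iterate E/M until the log-likelihood change drops below tol."""
        n = self.n_subjects
        for _ in range(max_iter):
            w = self.freq[self.r_h1] * self.freq[self.r_h2]
            denom = np.bincount(self.r_subj, weights=w, minlength=n)
            bad = denom <= 0
            if bad.any():  # resurrect orphaned subjects with uniform mass
                w = np.where(bad[self.r_subj], 1.0, w)
                denom = np.bincount(self.r_subj, weights=w, minlength=n)
            post = w / denom[self.r_subj]
            ll = float(np.log(denom[denom > 0]).sum())
            new_freq = (np.bincount(self.r_h1, weights=post,
                                    minlength=len(self.freq))
                        + np.bincount(self.r_h2, weights=post,
                                      minlength=len(self.freq))) / (2 * n)
            self.freq = new_freq / new_freq.sum()
            if ll - self.loglik < tol and np.isfinite(self.loglik):
                self.loglik = ll
                break
            self.loglik = ll

    def prune(self, row_tol: float = 1e-5, freq_tol: float = 1e-8) -> None:
        """Drop negligible phase expansions and haplotypes, keeping every
        subject's best row."""
        w = self.freq[self.r_h1] * self.freq[self.r_h2]
        denom = np.bincount(self.r_subj, weights=w, minlength=self.n_subjects)
        denom[denom <= 0] = 1.0
        post = w / denom[self.r_subj]
        keep = post >= row_tol
        # always keep each subject's highest-posterior row
        order = np.lexsort((post, self.r_subj))
        last_of_subj = np.ones(len(order), dtype=bool)
        last_of_subj[:-1] = self.r_subj[order][1:] != self.r_subj[order][:-1]
        keep[order[last_of_subj]] = True
        self.r_subj = self.r_subj[keep]
        self.r_h1, self.r_h2 = self.r_h1[keep], self.r_h2[keep]
        used = np.union1d(self.r_h1, self.r_h2)
        used = used[self.freq[used] >= 0]  # compaction index
        remap = -np.ones(len(self.freq), dtype=np.int64)
        remap[used] = np.arange(len(used))
        self.r_h1, self.r_h2 = remap[self.r_h1], remap[self.r_h2]
        self.hap_allele = self.hap_allele[used]
        self.hap_bits = self.hap_bits[used]
        freq = self.freq[used]
        freq[freq < freq_tol] = 0.0
        if freq.sum() == 0:
            freq[:] = 1.0
        self.freq = freq / freq.sum()

    def patterns(self) -> np.ndarray:
        """Haplotype SNP patterns as an (H, k) 0/1 matrix (bit t = SNP t)."""
        shifts = np.arange(self.k, dtype=np.int64)
        return ((self.hap_bits[:, None] >> shifts) & 1).astype(np.int8)


# ---------------------------------------------------------------------------
# classifiers and models


@dataclass
class Classifier:
    """One attribute-bagging member: SNP subset + haplotype frequency table."""

    snp_ids: list[str]
    snp_pos: list[int]
    patterns: np.ndarray = field(repr=False)   # H x k, 0/1
    alleles: list[str] = field(repr=False)     # per haplotype
    freqs: np.ndarray = field(repr=False)      # H, sums to 1
    oob_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.snp_ids) == 0:
            raise ValueError("empty SNP subset")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("classifier frequencies do not sum to 1")
        if (self.freqs < 0).any():
            raise ValueError("negative classifier frequency")

    @property
    def freq_table(self) -> dict[tuple[str, str], float]:
        """(pattern string, allele) -> frequency."""
        return {("".join(map(str, row)), a): float(f)
                for row, a, f in zip(self.patterns, self.alleles, self.freqs)}


@dataclass
class ImputationModel:
    gene: str
    resolution: int
    classifiers: list[Classifier]
    flank_bp: int = 500_000
    n_subjects: int = 0
    allele_list: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("model has no classifiers")


def _pair_posteriors(clf: Classifier, genotypes: np.ndarray
                     ) -> list[dict[tuple[str, str], float]]:
    """Normalized allele-pair posteriors per subject for one classifier.

    ``genotypes``: subjects x k dosages over the classifier SNPs, NaN for
    missing (marginalized over the frequency table).  Subjects whose
    genotype is incompatible with every table haplotype pair get an empty
    dict (the classifier abstains for them).
    """
    P = clf.patterns.astype(np.int16)
    H, k = P.shape
    key_pows = 1 << np.arange(k, dtype=np.int64)
    hap_key = P.astype(np.int64) @ key_pows
    by_key: dict[int, np.ndarray] = {}
    for h, key in enumerate(hap_key):
        by_key.setdefault(int(key), []).append(h)
    by_key = {key: np.asarray(v) for key, v in by_key.items()}

    enc = np.where(np.isnan(genotypes), 3, genotypes).astype(np.int8)
    uniq, inverse = np.unique(enc, axis=0, return_inverse=True)
    out_by_uniq: list[dict[tuple[str, str], float]] = []
    for g in uniq:
        miss = g == 3
        pairs: dict[tuple[str, str], float] = {}
        if not miss.any():
            req = g.astype(np.int16)[None, :] - P  # required partner bits
            valid = ((req == 0) | (req == 1)).all(axis=1)
            req_key = np.where(req == 1, 1, 0).astype(np.int64) @ key_pows
            for h1 in np.flatnonzero(valid):
                partners = by_key.get(int(req_key[h1]))
                if partners is None:
                    continue
                f1 = clf.freqs[h1]
                a1 = clf.alleles[h1]
                for h2 in partners:
                    pair = tuple(sorted((a1, clf.alleles[h2])))
                    pairs[pair] = pairs.get(pair, 0.0) + f1 * clf.freqs[h2]
        else:
            obs = ~miss
            for h1 in range(H):
                d = g.astype(np.int16) - P[h1]
                if ((d[obs] != 0) & (d[obs] != 1)).any():
                    continue
                match = (P[:, obs] == d[None, obs]).all(axis=1)
                f1 = clf.freqs[h1]
                a1 = clf.alleles[h1]
                for h2 in np.flatnonzero(match):
                    pair = tuple(sorted((a1, clf.alleles[h2])))
                    pairs[pair] = pairs.get(pair, 0.0) + f1 * clf.freqs[h2]
        total = sum(pairs.values())
        out_by_uniq.append({p: v / total for p, v in pairs.items()}
                           if total > 0 else {})
    return [out_by_uniq[i] for i in inverse]


def _best_pair(post: dict[tuple[str, str], float]
               ) -> tuple[tuple[str, str], float]:
    # deterministic: highest posterior, ties by lexicographic pair name
    return min(post.items(), key=lambda kv: (-kv[1], kv[0]))


def pair_match_count(truth: tuple[str, str], pred: tuple[str, str]) -> int:
    """Alleles shared between two unordered pairs, with multiplicity (0-2)."""
    t, p = list(truth), list(pred)
    n = 0
    for a in p:
        if a in t:
            t.remove(a)
            n += 1
    return n


def _typing_pairs(typing: pd.DataFrame, gene: str, resolution: int
                  ) -> pd.DataFrame:
    """Per-sample allele pairs truncated to the requested resolution."""
    sub = typing[typing["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no typing rows for gene {gene}")
    too_low = []
    rows = []
    for _, r in sub.iterrows():
        a1, a2 = parse_allele(r["allele1"]), parse_allele(r["allele2"])
        if min(a1.resolution, a2.resolution) < resolution:
            too_low.append(r["sample"])
            continue
        t1, t2 = str(truncate(a1, resolution)), str(truncate(a2, resolution))
        rows.append((r["sample"], *sorted((t1, t2))))
    if too_low:
        raise ValueError(
            f"typing resolution below {resolution} digits for samples: "
            f"{too_low}")
    return pd.DataFrame(rows, columns=["sample", "allele1", "allele2"])


def _flank_columns(gm: GenotypeMatrix, gene: str, flank_bp: int,
                   anchor_pos: int | None) -> np.ndarray:
    anchor = anchor_pos if anchor_pos is not None else GENE_ANCHORS.get(gene)
    if anchor is None:
        raise ValueError(f"no anchor position known for {gene}; pass anchor_pos")
    pos = gm.variants["pos"].to_numpy()
    cols = np.flatnonzero((pos >= anchor - flank_bp) & (pos <= anchor + flank_bp))
    # polymorphic SNPs only
    poly = [c for c in cols
            if np.nanstd(gm.dosage[:, c]) > 0]
    if not poly:
        raise ValueError(f"flank of {gene} has no polymorphic SNP")
    return np.asarray(poly)


def _oob_accuracy(clf_like: tuple[np.ndarray, list[str], np.ndarray],
                  genotypes: np.ndarray, truth_pairs: list[tuple[str, str]]
                  ) -> float:
    patterns, alleles, freqs = clf_like
    tmp = Classifier(snp_ids=["x"] * max(patterns.shape[1], 1) or ["x"],
                     snp_pos=[0] * max(patterns.shape[1], 1),
                     patterns=patterns, alleles=alleles, freqs=freqs)
    posts = _pair_posteriors(tmp, genotypes)
    n_ok = 0
    for post, truth in zip(posts, truth_pairs):
        if post:
            n_ok += pair_match_count(truth, _best_pair(post)[0])
    return n_ok / (2 * len(truth_pairs)) if truth_pairs else 0.0


def split_sizes(n: int, train_fraction: float = 0.7) -> tuple[int, int]:
    """Train/validation sizes for a fractional split (train = round(f*n))."""
    n_train = int(n * train_fraction + 0.5)
    return n_train, n - n_train


def em_joint_frequencies(snp_genotypes: np.ndarray, allele_pairs: list,
                         tol: float = 1e-10, max_iter: int = 2000
                         ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """EM over unphased (SNP genotype, allele pair) data on a fixed SNP set.

    Returns (haplotype patterns H x k, haplotype allele labels,
    frequencies).  The estimator behind each classifier, exposed for
    direct use and validation.
    """
    geno = np.asarray(snp_genotypes, float)
    alleles = sorted({a for pair in allele_pairs for a in pair})
    code = {a: i for i, a in enumerate(alleles)}
    pairs = np.array([[code[a], code[b]] for a, b in allele_pairs])
    state = _EMState(pairs, len(alleles))
    for j in range(geno.shape[1]):
        state.extend(geno[:, j])
        state.em(max_iter=max_iter, tol=tol)
    state.em(max_iter=max_iter, tol=tol)
    state.prune(row_tol=1e-9, freq_tol=1e-12)
    state.em(max_iter=max_iter, tol=tol)
    return (state.patterns(), [alleles[c] for c in state.hap_allele],
            state.freq)


def train_model(gm: GenotypeMatrix, typing: pd.DataFrame, gene: str,
                resolution: int = 4, n_classifiers: int = 100,
                flank_bp: int = 500_000, seed: int = 0,
                max_snps: int = 15, anchor_pos: int | None = None
                ) -> ImputationModel:
    """Train the attribute-bagging ensemble for one gene and resolution.

    Per classifier: bootstrap the typed subjects, grow a SNP subset
    greedily over the flank (each step adds the SNP maximizing
    out-of-bag allele-prediction accuracy, stopping when none improves
    it, capped at ``max_snps``), fit the haplotype-pattern x allele
    frequency table by EM, and record the out-of-bag accuracy.
    """
    pairs = _typing_pairs(typing, gene, resolution)
    sample_pos = {s: i for i, s in enumerate(gm.samples)}
    missing = [s for s in pairs["sample"] if s not in sample_pos]
    if missing:
        raise ValueError(f"typed samples absent from genotypes: {missing}")
    rows = np.array([sample_pos[s] for s in pairs["sample"]])
    alleles = sorted(set(pairs["allele1"]) | set(pairs["allele2"]))
    a_code = {a: i for i, a in enumerate(alleles)}
    allele_pairs = np.column_stack([
        [a_code[a] for a in pairs["allele1"]],
        [a_code[a] for a in pairs["allele2"]]])
    flank = _flank_columns(gm, gene, flank_bp, anchor_pos)
    dosage = gm.dosage[rows][:, flank]  # typed subjects x flank SNPs
    n = len(rows)
    rng = np.random.default_rng(seed)

    classifiers: list[Classifier] = []
    for _ in range(n_classifiers):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            oob = np.arange(n)
        oob_truth = [tuple(p) for p in np.array(
            [alleles[c] for c in allele_pairs[oob].ravel()]
        ).reshape(-1, 2)]
        oob_truth = [tuple(sorted(t)) for t in oob_truth]
        state = _EMState(allele_pairs[boot], len(alleles))
        state.em(max_iter=50, tol=1e-5)
        selected: list[int] = []
        best_acc = _oob_accuracy(
            (state.patterns(), [alleles[c] for c in state.hap_allele],
             state.freq),
            np.empty((len(oob), 0)), oob_truth)
        while len(selected) < max_snps:
            remaining = np.setdiff1d(flank, np.asarray(selected, dtype=int))
            if len(remaining) == 0:
                break
            scored = []
            for s in remaining:
                col = int(np.flatnonzero(flank == s)[0])
                st = state.copy()
                st.extend(dosage[boot, col])
                st.em(max_iter=30, tol=1e-4)
                st.prune()
                geno = dosage[np.ix_(oob, [int(np.flatnonzero(flank == c)[0])
                                           for c in selected + [s]])]
                acc = _oob_accuracy(
                    (st.patterns(), [alleles[c] for c in st.hap_allele],
                     st.freq), geno, oob_truth)
                scored.append((acc, int(s), st))
            acc, s, st = max(scored, key=lambda t: t[0])
            if selected and acc <= best_acc:
                break  # no remaining SNP improves OOB accuracy
            selected.append(s)
            state, best_acc = st, acc
        state.em(max_iter=500, tol=1e-7)
        state.prune(row_tol=1e-6, freq_tol=1e-8)
        classifiers.append(Classifier(
            snp_ids=[gm.variants["id"].iloc[c] for c in selected],
            snp_pos=[int(gm.variants["pos"].iloc[c]) for c in selected],
            patterns=state.patterns(),
            alleles=[alleles[c] for c in state.hap_allele],
            freqs=state.freq,
            oob_accuracy=float(best_acc)))
    return ImputationModel(gene=gene, resolution=resolution,
                           classifiers=classifiers, flank_bp=flank_bp,
                           n_subjects=n, allele_list=alleles, seed=seed)


def impute(model: ImputationModel, gm: GenotypeMatrix,
           call_threshold: float = 0.5) -> pd.DataFrame:
    """Ensemble-averaged allele-pair posteriors for every subject.

    Returns columns sample, gene, allele1, allele2, posterior, called.
    Model SNPs absent from ``gm`` are treated as missing genotypes and
    marginalized; if no model SNP overlaps ``gm`` an error is raised.
    """
    id_pos = {v: j for j, v in enumerate(gm.variants["id"])}
    if not any(s in id_pos for c in model.classifiers for s in c.snp_ids):
        raise ValueError("no overlap between model SNPs and genotype matrix")
    n = gm.n_samples
    sums: list[dict[tuple[str, str], float]] = [dict() for _ in range(n)]
    contrib = np.zeros(n)
    for clf in model.classifiers:
        cols = [id_pos.get(s) for s in clf.snp_ids]
        geno = np.full((n, len(cols)), np.nan)
        for t, c in enumerate(cols):
            if c is not None:
                geno[:, t] = gm.dosage[:, c]
        for i, post in enumerate(_pair_posteriors(clf, geno)):
            if post:
                contrib[i] += 1
                acc = sums[i]
                for pair, v in post.items():
                    acc[pair] = acc.get(pair, 0.0) + v
    rows = []
    for i, s in enumerate(gm.samples):
        if contrib[i] == 0:
            rows.append((s, model.gene, "", "", 0.0, False))
            continue
        post = {p: v / contrib[i] for p, v in sums[i].items()}
        (a1, a2), prob = _best_pair(post)
        rows.append((s, model.gene, a1, a2, float(prob),
                     bool(prob >= call_threshold)))
    return pd.DataFrame(rows, columns=["sample", "gene", "allele1", "allele2",
                                       "posterior", "called"])


def internal_validation(gm: GenotypeMatrix, typing: pd.DataFrame, gene: str,
                        resolution: int = 4, train_fraction: float = 0.7,
                        n_classifiers: int = 100, flank_bp: int = 500_000,
                        seed: int = 0, call_threshold: float = 0.5,
                        max_snps: int = 15, anchor_pos: int | None = None
                        ) -> tuple[float, float]:
    """Hold-out validation at a train:validation split (default 7:3).

    Returns (per-allele accuracy among called subjects, call rate).
    """
    pairs = _typing_pairs(typing, gene, resolution)
    if len(pairs) < 10:
        raise ValueError("need >= 10 typed subjects for internal validation")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train, _ = split_sizes(len(pairs), train_fraction)
    train_samples = set(pairs["sample"].iloc[order[:n_train]])
    valid_samples = [s for s in pairs["sample"] if s not in train_samples]
    train_typing = typing[typing["sample"].isin(train_samples)]
    model = train_model(gm, train_typing, gene, resolution,
                        n_classifiers=n_classifiers, flank_bp=flank_bp,
                        seed=seed, max_snps=max_snps, anchor_pos=anchor_pos)
    vrows = [gm.samples.index(s) for s in valid_samples]
    gm_valid = gm.subset(sample_idx=np.asarray(vrows))
    calls = impute(model, gm_valid, call_threshold=call_threshold)
    truth = {r["sample"]: tuple(sorted((r["allele1"], r["allele2"])))
             for _, r in pairs.iterrows()}
    unseen = {a for t in (truth[s] for s in valid_samples) for a in t
              if a not in model.allele_list}
    if unseen:
        warnings.warn(f"validation alleles absent from training: {sorted(unseen)}")
    n_called, n_match = 0, 0
    for _, r in calls.iterrows():
        if not r["called"]:
            continue
        n_called += 1
        n_match += pair_match_count(truth[r["sample"]],
                                    (r["allele1"], r["allele2"]))
    call_rate = n_called / len(valid_samples) if valid_samples else 0.0
    accuracy = n_match / (2 * n_called) if n_called else float("nan")
    return accuracy, call_rate


# ---------------------------------------------------------------------------
# serialization


def serialize_model(model: ImputationModel, path: str) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "gene": model.gene,
        "resolution": model.resolution,
        "flank_bp": model.flank_bp,
        "n_subjects": model.n_subjects,
        "allele_list": model.allele_list,
        "seed": model.seed,
        "classifiers": [
            {
                "snp_ids": c.snp_ids,
                "snp_pos": c.snp_pos,
                "patterns": ["".join(map(str, row)) for row in c.patterns],
                "alleles": c.alleles,
                "freqs": [repr(float(f)) for f in c.freqs],
                "oob_accuracy": c.oob_accuracy,
            }
            for c in model.classifiers
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> ImputationModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt or truncated model file {path}: {e}") from e
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version} != supported {MODEL_FORMAT_VERSION}")
    classifiers = [
        Classifier(
            snp_ids=c["snp_ids"],
            snp_pos=c["snp_pos"],
            patterns=np.array([[int(ch) for ch in row] for row in c["patterns"]],
                              dtype=np.int8).reshape(len(c["patterns"]),
                                                     len(c["snp_ids"])),
            alleles=c["alleles"],
            freqs=np.array([float(f) for f in c["freqs"]]),
            oob_accuracy=c["oob_accuracy"],
        )
        for c in doc["classifiers"]
    ]
    return ImputationModel(gene=doc["gene"], resolution=doc["resolution"],
                           classifiers=classifiers, flank_bp=doc["flank_bp"],
                           n_subjects=doc["n_subjects"],
                           allele_list=doc["allele_list"], seed=doc["seed"])
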