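"""Region-wide heritability and genetic correlation via Haseman-Elston regression.

A genetic relationship matrix (GRM) over the catalogue variants feeds the
classic product-moment HE estimators: the univariate slope of phenotype
cross-products y_i * y_j on GRM entries estimates h2, and the bivariate
slope of symmetrized cross-trait products estimates the genetic
covariance, giving r_g = cov_g / sqrt(h2_1 * h2_2).  Only off-diagonal
pairs (i < j) enter the regressions.  Standard errors come from a
delete-one-block jackknife over subjects (default 100 blocks).

Phenotypes are expected on the same scale the association stage tests:
covariate-residualized and inverse-normal transformed for quantitative
traits, observed 0/1 scale for binary traits (no liability transform;
flagged in the output).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GRM:
    """Symmetric subjects x subjects relationship matrix.

    Entries average standardized-dosage products over the variants
    non-missing in both subjects (``n_variants_used``).
    """

    samples: list[str]
    matrix: np.ndarray
    n_variants: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.samples),) * 2:
            raise ValueError("GRM shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM not symmetric")


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    se: float
    n: int
    method: str = "HE-univariate"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("SE must be positive")

    @property
    def h2_percent(self) -> str:
        """Percent with 2 decimals, e.g. '0.82%'."""
        return f"{100 * self.h2:.2f}%"


@dataclass
class GeneticCorrelation:
    trait1: str
    trait2: str
    rg: float
    se: float
    p: float
    q: float = float("nan")
    clamped: bool = False


def compute_grm(dosage: np.ndarray, samples: list[str] | None = None) -> GRM:
    """GRM from an additive dosage matrix (subjects x variants).

    Each variant is standardized to mean 0, variance 1 under its observed
    allele frequency, x = (d - 2p) / sqrt(2p(1-p)); missing dosages
    contribute 0 to the product sum and are excluded from the per-pair
    variant count.
    """
    d = np.asarray(dosage, float)
    n, m = d.shape
    obs = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2 * obs.sum(axis=0))
    with np.errstate(invalid="ignore"):
        keep = (p > 0) & (p < 1) & (np.nanvar(d, axis=0) > 0)
    if keep.sum() < 2:
        raise ValueError("need >= 2 polymorphic variants for a GRM")
    d, p, obs = d[:, keep], p[keep], obs[:, keep]
    x = (np.where(obs, d, 2 * p[None, :]) - 2 * p[None, :]) / \
        np.sqrt(2 * p * (1 - p))[None, :]
    counts = obs.astype(float) @ obs.T.astype(float)
    counts[counts == 0] = 1.0
    matrix = (x @ x.T) / counts
    matrix = (matrix + matrix.T) / 2
    return GRM(samples=samples or [f"S{i}" for i in range(n)],
               matrix=matrix, n_variants=int(keep.sum()))


# ---------------------------------------------------------------------------
# pair regressions with block jackknife


def _block_pair_sums(M: np.ndarray, block_ids: np.ndarray, n_blocks: int
                     ) -> tuple[float, np.ndarray]:
    """Total over unordered pairs i<j and, per block, the sum over pairs
    touching the block.  ``M`` must be symmetric with zero diagonal."""
    total = M.sum() / 2
    rows = M.sum(axis=1)
    touch = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = block_ids == b
        touch[b] = rows[mask].sum() - M[np.ix_(mask, mask)].sum() / 2
    return float(total), touch


def _pair_slope_jackknife(A: np.ndarray, P: np.ndarray,
                          block_ids: np.ndarray, n_blocks: int
                          ) -> tuple[float, float, np.ndarray]:
    """Slope of P on A over pairs i<j (with intercept), plus delete-one-
    block jackknife SE and the per-block slopes."""
    n = A.shape[0]
    ones = np.ones_like(A) - np.eye(n)
    sums = {}
    for name, M in (("n", ones), ("x", A * ones), ("y", P * ones),
                    ("xx", A * A * ones), ("xy", A * P * ones)):
        sums[name] = _block_pair_sums(M, block_ids, n_blocks)

    def slope(which) -> float:
        if which is None:
            N, Sx, Sy, Sxx, Sxy = (sums[k][0] for k in ("n", "x", "y", "xx", "xy"))
        else:
            N, Sx, Sy, Sxx, Sxy = (sums[k][0] - sums[k][1][which]
                                   for k in ("n", "x", "y", "xx", "xy"))
        denom = Sxx - Sx * Sx / N
        if denom <= 0:
            raise ValueError("no relatedness contrast in the GRM off-diagonal")
        return (Sxy - Sx * Sy / N) / denom

    full = slope(None)
    loo = np.array([slope(b) for b in range(n_blocks)])
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return full, se, loo


def _blocks(n: int, n_blocks: int) -> tuple[np.ndarray, int]:
    n_blocks = min(n_blocks, n)
    return np.arange(n) % n_blocks, n_blocks


def he_univariate(y: np.ndarray, grm: GRM, trait: str = "",
                  n_blocks: int = 100) -> HeritabilityEstimate:
    """Univariate HE regression: slope of y_i*y_j on GRM_ij over pairs i<j."""
    y = np.asarray(y, float)
    n = len(y)
    if n != len(grm.samples):
        raise ValueError("phenotype length does not match GRM")
    if n < 100:
        raise ValueError("need >= 100 subjects for HE regression")
    ok = ~np.isnan(y)
    y = y[ok]
    A = grm.matrix[np.ix_(ok, ok)].copy()
    np.fill_diagonal(A, 0.0)
    yc = y - y.mean()
    P = np.outer(yc, yc)
    np.fill_diagonal(P, 0.0)
    block_ids, n_blocks = _blocks(len(y), n_blocks)
    h2, se, _ = _pair_slope_jackknife(A, P, block_ids, n_blocks)
    return HeritabilityEstimate(trait=trait, h2=float(h2), se=max(se, 1e-12),
                                n=len(y))


def he_bivariate(y1: np.ndarray, y2: np.ndarray, grm: GRM,
                 trait1: str = "", trait2: str = "",
                 n_blocks: int = 100) -> GeneticCorrelation:
    """Bivariate HE regression on the shared complete-case subject subset.

    The genetic covariance is the slope of the symmetrized cross-products
    (y1_i*y2_j + y1_j*y2_i)/2 on GRM_ij; r_g = cov_g / sqrt(h2_1*h2_2),
    clamped to [-1, 1] with the clamp recorded.  The p-value uses the
    jackknife SE of r_g itself.  NaN r_g when either h2 <= 0.
    """
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)
    ok = ~(np.isnan(y1) | np.isnan(y2))
    y1, y2 = y1[ok], y2[ok]
    n = len(y1)
    if n < 100:
        raise ValueError("need >= 100 subjects for HE regression")
    A = grm.matrix[np.ix_(ok, ok)].copy()
    np.fill_diagonal(A, 0.0)
    c1, c2 = y1 - y1.mean(), y2 - y2.mean()
    P11 = np.outer(c1, c1)
    P22 = np.outer(c2, c2)
    P12 = (np.outer(c1, c2) + np.outer(c2, c1)) / 2
    for P in (P11, P22, P12):
        np.fill_diagonal(P, 0.0)
    block_ids, n_blocks = _blocks(n, n_blocks)
    h1, _, loo1 = _pair_slope_jackknife(A, P11, block_ids, n_blocks)
    h2_, _, loo2 = _pair_slope_jackknife(A, P22, block_ids, n_blocks)
    cov, _, loo12 = _pair_slope_jackknife(A, P12, block_ids, n_blocks)
    if h1 <= 0 or h2_ <= 0:
        return GeneticCorrelation(trait1=trait1, trait2=trait2,
                                  rg=float("nan"), se=float("nan"),
                                  p=float("nan"))
    rg = cov / np.sqrt(h1 * h2_)
    with np.errstate(invalid="ignore"):
        loo_rg = np.where((loo1 > 0) & (loo2 > 0),
                          loo12 / np.sqrt(loo1 * loo2), rg)
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * ((loo_rg - loo_rg.mean()) ** 2).sum()))
    clamped = bool(abs(rg) > 1)
    rg_c = float(np.clip(rg, -1.0, 1.0))
    if se > 0:
        p = float(2 * stats.norm.sf(abs(rg) / se))
    else:
        p = 0.0 if rg != 0 else 1.0
    return GeneticCorrelation(trait1=trait1, trait2=trait2, rg=rg_c,
                              se=se, p=p, clamped=clamped)


def correlation_network(correlations: list[GeneticCorrelation],
                        alpha: float = 0.05) -> nx.Graph:
    """Benjamini-Hochberg FDR across all tested pairs; edges are pairs with
    q < alpha, weighted by r_g (sign preserved); nodes need >= 1 edge."""
    tested = [c for c in correlations if np.isfinite(c.p)]
    graph = nx.Graph()
    if not tested:
        return graph
    pvals = np.array([c.p for c in tested])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for c, q in zip(tested, qvals):
        c.q = float(q)
        if q < alpha:
            graph.add_edge(c.trait1, c.trait2, weight=c.rg, rg=c.rg,
                           p=c.p, q=c.q)
    return graph


def network_edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"trait1": u, "trait2": v, "rg": d["rg"], "p": d["p"], "q": d["q"]}
            for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["trait1", "trait2", "rg", "p", "q"])
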