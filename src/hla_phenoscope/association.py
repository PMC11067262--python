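"""The PheWAS engine.

Binary traits: additive logistic regression with sex, age, age^2 and ten
principal components as covariates, with a Firth penalized fallback when
the unpenalized fit separates or fails to converge.  Quantitative traits:
covariates are regressed out first, the residuals are rank-based
inverse-normal transformed (Blom offset 3/8), and the transformed
residuals are tested against dosage by OLS.  Multiallelic amino-acid
positions are tested with an omnibus likelihood-ratio test against the
covariate-only null: chi-square with n - 1 degrees of freedom at a
position with n residues, the most frequent residue serving as reference.

Genome-wide significance is the conventional p < 5e-8; no further
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri, expit

DEFAULT_COVARIATES = ("sex", "age", "age2",
                      "PC1", "PC2", "PC3", "PC4", "PC5",
                      "PC6", "PC7", "PC8", "PC9", "PC10")
GWS_THRESHOLD = 5e-8


@dataclass
class AssociationResult:
    variant_id: str
    trait: str
    effect: float          # beta (quantitative) or log-OR (binary)
    se: float
    p: float
    n: int
    trait_type: str
    or_: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = "wald"
    gws: bool = False

    def __post_init__(self) -> None:
        self.gws = bool(self.p < GWS_THRESHOLD)


@dataclass
class OmnibusResult:
    gene: str
    position: int
    trait: str
    n_residues: int
    statistic: float
    df: int
    p: float
    trait_type: str
    dropped_residues: tuple[str, ...] = ()
    gws: bool = False

    def __post_init__(self) -> None:
        self.gws = bool(self.p < GWS_THRESHOLD)


# ---------------------------------------------------------------------------
# transforms and fitting primitives


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Blom offset:
    Phi^-1((rank - 3/8) / (n + 1/4)) with average ranks for ties.
    Missing values are preserved as NaN."""
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing values")
    x = v[obs]
    if np.all(x == x[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(x, method="average")
    out = np.full_like(v, np.nan)
    out[obs] = ndtri((ranks - 0.375) / (n + 0.25))
    return out


def _design(covariates: np.ndarray | None, n: int,
            *extra_cols: np.ndarray) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None and covariates.size:
        cols.append(np.atleast_2d(covariates.T).T
                    if covariates.ndim > 1 else covariates[:, None])
    for c in extra_cols:
        cols.append(c[:, None] if c.ndim == 1 else c)
    return np.column_stack(cols)


def _check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        if names is None:
            raise ValueError("collinear design matrix")
        # name the first column that adds no rank
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValueError(f"collinear covariate column: {names[j - 1]}")


def ols_fit(X: np.ndarray, y: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS via normal equations: (beta, se, rss) with classical SEs."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = len(y) - X.shape[1]
    sigma2 = rss / dof if dof > 0 else np.nan
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    if not (np.isfinite(beta).all() and np.isfinite(se).all()):
        raise np.linalg.LinAlgError("singular design matrix")
    return beta, se, rss


def logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_mle(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic MLE: (beta, se, converged)."""
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        score = X.T @ (y - p)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    info = (X * (p * (1 - p))[:, None]).T @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    huge = (not np.all(np.isfinite(se))) or np.max(np.abs(beta)) > 15
    return beta, se, converged and not huge


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth penalized logistic regression (Jeffreys-prior score correction).

    Keeps estimates finite under separation, which rare alleles crossed
    with rare traits produce routinely.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        info = (X * W[:, None]).T @ X
        inv = np.linalg.inv(info)
        # leverage of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], inv,
                      X * np.sqrt(W)[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        step = inv @ score
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(X @ beta)
    info = (X * (p * (1 - p))[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


# ---------------------------------------------------------------------------
# single-variant tests


def _complete_cases(*arrays: np.ndarray | None) -> np.ndarray:
    ok = None
    for a in arrays:
        if a is None:
            continue
        miss = np.isnan(a).any(axis=1) if a.ndim > 1 else np.isnan(a)
        ok = miss if ok is None else (ok | miss)
    return ~ok


def logistic_assoc(dosage: np.ndarray, y: np.ndarray,
                   covariates: np.ndarray | None = None,
                   variant_id: str = "", trait: str = "",
                   condition_on: np.ndarray | None = None
                   ) -> AssociationResult:
    """Additive logistic regression of a binary trait on dosage.

    Firth fallback on separation or non-convergence.  ``condition_on``
    adds extra covariate columns (used by the conditional scan).
    """
    dosage = np.asarray(dosage, float)
    y = np.asarray(y, float)
    ok = _complete_cases(dosage, y, covariates, condition_on)
    d, yy = dosage[ok], y[ok]
    cov = covariates[ok] if covariates is not None else None
    extra = condition_on[ok] if condition_on is not None else None
    if d.std() == 0:
        raise ValueError(f"zero variance dosage for {variant_id or 'variant'}")
    classes = np.unique(yy)
    if len(classes) < 2:
        raise ValueError("binary trait has a single class after missing-data removal")
    parts = [np.ones(len(yy)), d]  # dosage fixed at column 1
    if extra is not None:
        parts.append(extra if extra.ndim > 1 else extra[:, None])
    if cov is not None and cov.size:
        parts.append(cov if cov.ndim > 1 else cov[:, None])
    X = np.column_stack(parts)
    beta, se, converged = logistic_mle(X, yy)
    method = "wald"
    if not converged:
        beta, se = firth_logistic(X, yy)
        method = "firth"
    j = 1  # dosage column
    z = beta[j] / se[j]
    p = 2 * stats.norm.sf(abs(z))
    return AssociationResult(
        variant_id=variant_id, trait=trait, effect=float(beta[j]),
        se=float(se[j]), p=float(p), n=int(ok.sum()), trait_type="binary",
        or_=float(np.exp(beta[j])),
        ci_low=float(np.exp(beta[j] - 1.96 * se[j])),
        ci_high=float(np.exp(beta[j] + 1.96 * se[j])),
        method=method)


def residualize(y: np.ndarray, covariates: np.ndarray | None,
                covariate_names: list[str] | None = None) -> np.ndarray:
    """Stage 1+2 for quantitative traits: OLS residuals on the covariates,
    then the rank-based inverse-normal transform.  NaN preserved."""
    y = np.asarray(y, float)
    ok = _complete_cases(y, covariates)
    X = _design(covariates[ok] if covariates is not None else None,
                int(ok.sum()))
    names = ["intercept"] + list(covariate_names or
                                 [f"cov{j}" for j in range(X.shape[1] - 1)])
    _check_full_rank(X, names)
    beta, _, _ = ols_fit(X, y[ok])
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - X @ beta
    out = np.full_like(y, np.nan)
    out[ok] = inverse_normal_transform(resid[ok])
    return out


def quantitative_assoc(dosage: np.ndarray, y: np.ndarray,
                       covariates: np.ndarray | None = None,
                       variant_id: str = "", trait: str = "",
                       y_is_transformed: bool = False,
                       covariate_names: list[str] | None = None,
                       condition_on: np.ndarray | None = None
                       ) -> AssociationResult:
    """Covariate-residualized inverse-normal OLS association.

    Stage 1: OLS of y on covariates; stage 2: inverse-normal transform of
    the residuals; stage 3: OLS of the transformed residuals on dosage.
    Pass ``y_is_transformed=True`` to reuse precomputed residuals.
    ``condition_on`` columns join the stage-3 regression.
    """
    dosage = np.asarray(dosage, float)
    z = (np.asarray(y, float) if y_is_transformed
         else residualize(y, covariates, covariate_names))
    ok = _complete_cases(dosage, z, condition_on)
    d, zz = dosage[ok], z[ok]
    if d.std() == 0:
        raise ValueError(f"zero variance dosage for {variant_id or 'variant'}")
    cols = [d] if condition_on is None else [d, condition_on[ok]]
    X = _design(None, len(zz), *cols)
    beta, se, _ = ols_fit(X, zz)
    dof = len(zz) - X.shape[1]
    t = beta[1] / se[1]
    p = 2 * stats.t.sf(abs(t), dof)
    return AssociationResult(
        variant_id=variant_id, trait=trait, effect=float(beta[1]),
        se=float(se[1]), p=float(p), n=int(ok.sum()),
        trait_type="quantitative")


def omnibus_test(position_dosages: np.ndarray, y: np.ndarray,
                 covariates: np.ndarray | None, trait_type: str,
                 residues: list[str] | None = None,
                 gene: str = "", position: int = 0, trait: str = "",
                 y_is_transformed: bool = False) -> OmnibusResult:
    """Omnibus likelihood-ratio test at one amino-acid position.

    ``position_dosages`` is residues x subjects.  The most frequent
    residue (tie: lexicographically first) is the reference; the full
    model adds the remaining n - 1 residue dosages to the null
    (covariate-only) model.  The statistic follows chi-square with
    df = n - 1, reduced when collinear residues must be dropped.
    """
    D = np.asarray(position_dosages, float)
    n_res = D.shape[0]
    if n_res < 2:
        raise ValueError("omnibus test needs >= 2 residues")
    residues = residues or [f"res{k}" for k in range(n_res)]
    totals = np.nansum(D, axis=1)
    ref = min(range(n_res), key=lambda k: (-totals[k], residues[k]))
    keep = [k for k in range(n_res) if k != ref]
    y = np.asarray(y, float)
    if trait_type == "quantitative" and not y_is_transformed:
        y = residualize(y, covariates)
        covariates = None
    ok = _complete_cases(y, D.T, covariates)
    yy = y[ok]
    R = D[:, ok].T[:, keep]  # subjects x (n-1) residue dosages
    cov = covariates[ok] if (covariates is not None and
                             trait_type == "binary") else None
    # drop collinear residue columns, reducing df
    dropped: list[str] = []
    base = _design(cov, len(yy))
    cols = list(range(R.shape[1]))
    while cols:
        X = np.column_stack([base, R[:, cols]])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        j = cols[-1]
        for c in cols:  # find a column that adds no rank
            others = [cc for cc in cols if cc != c]
            Xo = np.column_stack([base, R[:, others]]) if others else base
            if np.linalg.matrix_rank(Xo) == np.linalg.matrix_rank(X):
                j = c
                break
        dropped.append(residues[keep[j]])
        cols.remove(j)
    if dropped:
        warnings.warn(f"collinear residues dropped at {gene} pos {position}: "
                      f"{dropped}")
    df = len(cols)
    if df == 0:
        return OmnibusResult(gene=gene, position=position, trait=trait,
                             n_residues=n_res, statistic=0.0, df=0, p=1.0,
                             trait_type=trait_type,
                             dropped_residues=tuple(dropped))
    X_full = np.column_stack([base, R[:, cols]])
    if trait_type == "binary":
        b0, _, c0 = logistic_mle(base, yy)
        b1, _, c1 = logistic_mle(X_full, yy)
        ll0 = logistic_loglik(base, yy, b0)
        ll1 = logistic_loglik(X_full, yy, b1)
        stat = max(0.0, 2 * (ll1 - ll0))
    elif trait_type == "quantitative":
        _, _, rss0 = ols_fit(base, yy)
        _, _, rss1 = ols_fit(X_full, yy)
        stat = max(0.0, len(yy) * np.log(rss0 / rss1))
    else:
        raise ValueError(f"unknown trait type {trait_type!r}")
    p = float(stats.chi2.sf(stat, df))
    return OmnibusResult(gene=gene, position=position, trait=trait,
                         n_residues=n_res, statistic=float(stat), df=df, p=p,
                         trait_type=trait_type, dropped_residues=tuple(dropped))


# ---------------------------------------------------------------------------
# the scan


def covariate_matrix(phenotypes: pd.DataFrame,
                     names: tuple[str, ...] = DEFAULT_COVARIATES) -> np.ndarray:
    present = [c for c in names if c in phenotypes.columns]
    return phenotypes[present].to_numpy(dtype=float)


def run_phewas(catalogue, phenotypes: pd.DataFrame,
               binary_traits: list[str] | None = None,
               quantitative_traits: list[str] | None = None,
               covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
               gws: float = GWS_THRESHOLD
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All biallelic variants x all traits, plus omnibus tests at every
    multiallelic position.  Returns (association table, omnibus table)."""
    binary_traits = binary_traits if binary_traits is not None else []
    quantitative_traits = (quantitative_traits
                           if quantitative_traits is not None else [])
    cov = covariate_matrix(phenotypes, covariate_names)
    rows, orows = [], []
    trait_vectors: dict[str, tuple[str, np.ndarray]] = {}
    for t in binary_traits:
        yv = phenotypes[t].to_numpy(dtype=float)
        if np.nansum(yv) == 0 or np.nansum(1 - yv) == 0:
            warnings.warn(f"trait {t!r} has a single class; skipped")
            continue
        trait_vectors[t] = ("binary", yv)
    for t in quantitative_traits:
        yv = phenotypes[t].to_numpy(dtype=float)
        trait_vectors[t] = ("quantitative",
                            residualize(yv, cov, list(covariate_names)))
    for trait, (ttype, yv) in trait_vectors.items():
        for j, meta in catalogue.biallelic.iterrows():
            d = catalogue.dosage[:, j]
            try:
                if ttype == "binary":
                    res = logistic_assoc(d, yv, cov, variant_id=meta["id"],
                                         trait=trait)
                else:
                    res = quantitative_assoc(d, yv, variant_id=meta["id"],
                                             trait=trait, y_is_transformed=True)
            except ValueError:
                continue
            rows.append({**res.__dict__, "source": meta["source"],
                         "gene": meta["gene"]})
        for pos in catalogue.multiallelic:
            res = omnibus_test(pos.dosage, yv,
                               cov if ttype == "binary" else None,
                               ttype, residues=pos.residues, gene=pos.gene,
                               position=pos.position, trait=trait,
                               y_is_transformed=(ttype == "quantitative"))
            orows.append(res.__dict__.copy())
    assoc = pd.DataFrame(rows)
    omni = pd.DataFrame(orows)
    if len(assoc):
        assoc["gws"] = assoc["p"] < gws
    if len(omni):
        omni["gws"] = omni["p"] < gws
    return assoc, omni
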