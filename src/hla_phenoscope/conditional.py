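"""Forward-type stepwise conditional association with LD-linked covariates.

At each step the top remaining genome-wide-significant variant is selected
and entered into the covariate set together with every HLA allele and
amino-acid polymorphism in high LD (r^2 >= 0.7) with it; SNV/indel
companions are reported but never conditioned on.  Iteration stops when no
remaining variant reaches significance.  Variants in complete LD (r^2 = 1)
with a selected top signal are reported alongside it as co-top signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .association import (GWS_THRESHOLD, logistic_assoc, quantitative_assoc,
                          residualize)
from .variant_encoding import VariantCatalogue, ld_r2


@dataclass
class ConditionalStep:
    iteration: int
    variant_id: str
    source: str
    effect: float
    se: float
    p: float
    covariates_added: list[str]          # the variant + its HLA companions
    complete_ld_companions: list[str] = field(default_factory=list)
    truncated: bool = False


def complete_ld_companions(variant_id: str, catalogue: VariantCatalogue,
                           tol: float = 1e-12) -> list[str]:
    """All other catalogue variants with r^2 = 1 (within tol) to the variant."""
    target = catalogue.dosage_of(variant_id)
    out = []
    for j, other in enumerate(catalogue.biallelic["id"]):
        if other == variant_id:
            continue
        try:
            r2 = ld_r2(target, catalogue.dosage[:, j])
        except ValueError:
            continue
        if not np.isnan(r2) and r2 >= 1.0 - tol:
            out.append(other)
    return out


def _hla_companions(variant_id: str, catalogue: VariantCatalogue,
                    r2_threshold: float) -> list[str]:
    """HLA alleles and AA polymorphisms in LD >= threshold with the variant."""
    target = catalogue.dosage_of(variant_id)
    src = catalogue.biallelic["source"].to_numpy()
    out = []
    for j in np.flatnonzero(np.isin(src, ("hla_allele", "aa_residue"))):
        other = catalogue.biallelic["id"].iloc[j]
        if other == variant_id:
            continue
        try:
            r2 = ld_r2(target, catalogue.dosage[:, j])
        except ValueError:
            continue
        if not np.isnan(r2) and r2 >= r2_threshold:
            out.append(other)
    return out


def forward_conditional(trait: str, trait_type: str,
                        catalogue: VariantCatalogue, phenotypes,
                        covariate_names=None, r2_threshold: float = 0.7,
                        gws: float = GWS_THRESHOLD, max_iter: int = 20
                        ) -> list[ConditionalStep]:
    """Iterative conditional scan for one trait.

    Quantitative traits are residualized against the base covariates once;
    conditioning dosages then enter the final-stage regression alongside
    the test dosage, keeping the null fixed across iterations.
    """
    from .association import covariate_matrix, DEFAULT_COVARIATES

    cov = covariate_matrix(phenotypes, covariate_names or DEFAULT_COVARIATES)
    y = phenotypes[trait].to_numpy(dtype=float)
    if trait_type == "quantitative":
        y = residualize(y, cov)
    ids = catalogue.biallelic["id"].to_numpy()
    sources = catalogue.biallelic["source"].to_numpy()
    selected: set[str] = set()
    cond_ids: list[str] = []     # covariate dosage columns accumulated
    steps: list[ConditionalStep] = []
    for it in range(1, max_iter + 1):
        cond = (np.column_stack([_impute_mean(catalogue.dosage_of(v))
                                 for v in cond_ids])
                if cond_ids else None)
        best = None
        for j, vid in enumerate(ids):
            if vid in selected or vid in cond_ids:
                continue
            d = catalogue.dosage[:, j]
            try:
                if trait_type == "binary":
                    res = logistic_assoc(d, y, cov, variant_id=vid,
                                         trait=trait, condition_on=cond)
                else:
                    res = quantitative_assoc(d, y, variant_id=vid, trait=trait,
                                             y_is_transformed=True,
                                             condition_on=cond)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not np.isfinite(res.p):
                continue
            key = (res.p, vid)
            if best is None or key < best[0]:
                best = (key, j, res)
        if best is None or best[2].p >= gws:
            break
        _, j, res = best
        vid = ids[j]
        companions = _hla_companions(vid, catalogue, r2_threshold)
        added = [vid] + [c for c in companions if c not in cond_ids]
        new_cond = cond_ids + [v for v in added if v not in cond_ids]
        # guard against rank deficiency in the accumulated covariates
        M = np.column_stack([_impute_mean(catalogue.dosage_of(v))
                             for v in new_cond])
        keep_cols = _independent_columns(M)
        if len(keep_cols) < len(new_cond):
            dropped = [new_cond[k] for k in range(len(new_cond))
                       if k not in keep_cols]
            warnings.warn(f"collinear conditioning covariates dropped: {dropped}")
            new_cond = [new_cond[k] for k in keep_cols]
        cond_ids = new_cond
        selected.add(vid)
        steps.append(ConditionalStep(
            iteration=it, variant_id=vid, source=sources[j],
            effect=res.effect, se=res.se, p=res.p,
            covariates_added=added,
            complete_ld_companions=complete_ld_companions(vid, catalogue)))
    else:
        if steps:
            steps[-1].truncated = True
    return steps


def _impute_mean(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d), d)
    return d


def _independent_columns(M: np.ndarray) -> list[int]:
    """Greedy maximal set of columns independent of each other and of the
    intercept (regressions always carry one)."""
    ones = np.ones((M.shape[0], 1))
    keep: list[int] = []
    for j in range(M.shape[1]):
        trial = keep + [j]
        X = np.column_stack([ones, M[:, trial]])
        if np.linalg.matrix_rank(X) == len(trial) + 1:
            keep.append(j)
    return keep
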