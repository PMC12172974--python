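"""Covariate-adjusted linear associations of component expression scores
with context and outcome phenotypes.

Each model is an OLS of a standardized outcome on the standardized
predictor score plus covariates and site fixed-effect indicators; the
reported beta is the predictor's standardized coefficient with its
classical two-sided t-test p-value.  p-values are reported per outcome
without multiple-testing correction (flagged in the docs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    outcome_label: str
    beta: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def _site_dummies(site_labels: Sequence, n: int) -> tuple[np.ndarray, list[str]]:
    sites = pd.Series(np.asarray(site_labels))
    counts = sites.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        logger.warning(
            "site(s) %s have a single participant; folded into the reference level",
            singletons,
        )
        sites = sites.where(~sites.isin(singletons), counts.index[0])
    levels = sites.value_counts().index.tolist()   # most frequent = reference
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((sites == lev).to_numpy(dtype=float))
        names.append(f"site[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((n, 0)), names


def _build_design(
    predictor: np.ndarray,
    covariates: np.ndarray | None,
    site_labels: Sequence | None,
    extra: np.ndarray | None,
    n: int,
):
    parts = [np.ones((n, 1)), _zscore(predictor)[:, None]]
    names = ["const", "predictor"]
    if covariates is not None and np.asarray(covariates).size:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        parts.append(C)
        names += [f"cov{j}" for j in range(C.shape[1])]
    if extra is not None and np.asarray(extra).size:
        E = np.asarray(extra, dtype=float)
        if E.ndim == 1:
            E = E[:, None]
        parts.append(E)
        names += [f"adj{j}" for j in range(E.shape[1])]
    if site_labels is not None:
        S, snames = _site_dummies(site_labels, n)
        if S.shape[1]:
            parts.append(S)
            names += snames
    X = np.column_stack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear design: rank {rank} < {X.shape[1]} columns ({names})"
        )
    return X, names


def associate(
    outcome: np.ndarray,
    predictor_score: np.ndarray,
    covariates: np.ndarray | None = None,
    site_labels: Sequence | None = None,
    outcome_label: str = "outcome",
    extra_adjusters: np.ndarray | None = None,
) -> AssociationResult:
    """Standardized OLS association of an outcome with a predictor score,
    adjusting for covariates and site fixed effects."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor_score, dtype=float)
    if y.size != x.size:
        raise ValueError("outcome and predictor must align")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("complete cases required; drop missing rows first")
    X, _ = _build_design(x, covariates, site_labels, extra_adjusters, y.size)
    fit = sm.OLS(_zscore(y), X).fit()
    return AssociationResult(
        outcome_label=outcome_label,
        beta=float(fit.params[1]),
        p_value=float(np.clip(fit.pvalues[1], np.nextafter(0, 1), 1.0)),
        n=int(y.size),
    )


def adjusted_association(
    target: np.ndarray,
    predictor_score: np.ndarray,
    covariates: np.ndarray | None,
    extra_adjusters: np.ndarray,
    site_labels: Sequence | None = None,
    outcome_label: str = "target",
) -> AssociationResult:
    """Re-estimate the predictor's beta conditional on additional
    adjustment columns (context and behavior variables)."""
    return associate(
        target,
        predictor_score,
        covariates=covariates,
        site_labels=site_labels,
        outcome_label=outcome_label,
        extra_adjusters=extra_adjusters,
    )


def associate_many(
    pheno: pd.DataFrame,
    predictor_score: np.ndarray,
    outcomes: Sequence[str],
    covariates: np.ndarray | None = None,
    site_labels: Sequence | None = None,
) -> pd.DataFrame:
    """One covariate-adjusted association per outcome column."""
    rows = []
    for out in outcomes:
        res = associate(
            pheno[out].to_numpy(dtype=float),
            predictor_score,
            covariates=covariates,
            site_labels=site_labels,
            outcome_label=out,
        )
        rows.append({"outcome": out, "beta": res.beta, "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)
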