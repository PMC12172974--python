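"""Latent sleep-duration scores from three noisy indicators.

Weekly sleep duration is measured three ways (parent report, youth
report, wearable), each with its own bias and noise.  A single-factor
measurement model over the standardized indicators captures their shared
variance; the latent factor score is the sleep-duration estimate purged
of indicator-specific measurement error.  Weekday/weekend schedules are
first collapsed to a weekly average with calendar weights 5/7 and 2/7.

Maximum-likelihood estimation is delegated to
:class:`statsmodels.multivariate.factor.Factor`; factor scores are
computed here (regression method by default, Bartlett optional) and
standardized.  The downstream prediction target is *shorter* sleep, i.e.
the negated standardized factor score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

logger = logging.getLogger(__name__)

SLEEP_COLUMNS = ("sleep_parent", "sleep_youth", "sleep_fitbit")


@dataclass
class FactorModel:
    """One-factor measurement model over standardized indicators."""

    loadings: np.ndarray            # length 3, sign-fixed so the mean is positive
    uniquenesses: np.ndarray
    scores: np.ndarray              # standardized (mean 0, var 1)
    indicator_names: tuple[str, ...]
    indicator_means: np.ndarray
    indicator_sds: np.ndarray
    composite_correlation: float    # corr(scores, equal-weight composite)

    @property
    def communalities(self) -> np.ndarray:
        return self.loadings**2


def weekly_average(weekday_hours: float, weekend_hours: float) -> float:
    """Calendar-weighted weekly sleep duration: (5*weekday + 2*weekend)/7."""
    for name, v in (("weekday", weekday_hours), ("weekend", weekend_hours)):
        if not (0 < v < 24):
            raise ValueError(f"{name} hours must lie in (0, 24), got {v}")
    return (5.0 * weekday_hours + 2.0 * weekend_hours) / 7.0


def _standardize_indicators(table: pd.DataFrame, columns) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = table.loc[:, list(columns)].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(columns, sd) if s == 0]
        raise ValueError(f"indicator(s) with zero variance: {bad}")
    return (X - mu) / sd, mu, sd


def weighted_composite(table: pd.DataFrame, columns=SLEEP_COLUMNS) -> np.ndarray:
    """Equal-weight mean of the standardized indicators (complete cases);
    the diagnostic comparator for the factor scores."""
    sub = table.loc[:, list(columns)].dropna()
    Z, _, _ = _standardize_indicators(sub, columns)
    return Z.mean(axis=1)


def fit_sleep_factor(
    table: pd.DataFrame,
    columns=SLEEP_COLUMNS,
    method: str = "ml",
    score_method: str = "regression",
    min_cases: int = 50,
) -> FactorModel:
    """One-factor fit on the standardized complete-case indicators.

    ``method`` is ``"ml"`` (maximum likelihood, default) or ``"pa"``
    (principal axis); ``score_method`` is ``"regression"`` or
    ``"bartlett"``.  Loading signs are fixed so the mean loading is
    positive; scores are standardized to mean 0 / variance 1.
    """
    sub = table.loc[:, list(columns)].dropna()
    if len(sub) < min_cases:
        raise ValueError(f"need >= {min_cases} complete cases, got {len(sub)}")
    Z, mu, sd = _standardize_indicators(sub, columns)

    res = Factor(Z, n_factor=1, method=method).fit()
    lam = np.asarray(res.loadings[:, 0], dtype=float)
    psi = np.asarray(res.uniqueness, dtype=float)
    if not np.all(np.isfinite(lam)) or not np.all(np.isfinite(psi)):
        raise RuntimeError(
            f"factor fit did not converge (method={method}); "
            f"loadings={lam}, uniqueness={psi}"
        )
    heywood = np.flatnonzero(psi <= 0)
    if heywood.size:
        bad = [columns[i] for i in heywood]
        raise ValueError(f"Heywood case: nonpositive uniqueness for indicator(s) {bad}")
    if lam.mean() < 0:
        lam = -lam

    if score_method == "regression":
        R = np.corrcoef(Z, rowvar=False)
        # pinv covers the degenerate perfectly-collinear (noise-free) case
        weights = np.linalg.pinv(R) @ lam
    elif score_method == "bartlett":
        wpsi = lam / psi
        weights = wpsi / (lam @ wpsi)
    else:
        raise ValueError(f"unknown score method {score_method!r}")
    scores = Z @ weights
    scores = (scores - scores.mean()) / scores.std()

    composite = Z.mean(axis=1)
    comp_r = float(np.corrcoef(scores, composite)[0, 1])
    logger.info(
        "sleep factor: loadings=%s uniquenesses=%s corr(scores, composite)=%.4f",
        np.round(lam, 4), np.round(psi, 4), comp_r,
    )
    return FactorModel(
        loadings=lam,
        uniquenesses=psi,
        scores=scores,
        indicator_names=tuple(columns),
        indicator_means=mu,
        indicator_sds=sd,
        composite_correlation=comp_r,
    )


def add_sleep_scores(
    pheno: pd.DataFrame, columns=SLEEP_COLUMNS, **fit_kwargs
) -> tuple[pd.DataFrame, FactorModel]:
    """Return a copy of the phenotype table with ``sleep_factor``,
    ``sleep_composite`` and ``sleep_deficit`` (= negated factor score, the
    shorter-sleep prediction target) columns, complete cases only."""
    out = pheno.copy()
    complete = out.loc[:, list(columns)].notna().all(axis=1)
    model = fit_sleep_factor(out.loc[complete], columns, **fit_kwargs)
    out.loc[complete, "sleep_factor"] = model.scores
    out.loc[complete, "sleep_composite"] = weighted_composite(out.loc[complete], columns)
    out.loc[complete, "sleep_deficit"] = -model.scores
    return out, model


def factor_report(model: FactorModel) -> str:
    """Small text summary of a fitted sleep factor."""
    lines = ["sleep factor fit (one factor, standardized indicators)"]
    for name, lo, un in zip(model.indicator_names, model.loadings, model.uniquenesses):
        lines.append(f"  {name:<14s} loading={lo:+.4f}  uniqueness={un:.4f}")
    lines.append(f"  corr(factor scores, equal-weight composite) = {model.composite_correlation:.4f}")
    return "\n".join(lines)
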