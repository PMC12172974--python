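"""Parcellated time series -> participant correlation matrices.

Nuisance removal follows the single-step scheme used in developmental
resting-state cohorts: the linear trend, all confound columns, a
discrete-cosine high-pass basis, and one spike regressor per censored
volume are projected out of every parcel series in one least-squares fit.
Correlations are then computed over the retained (uncensored) volumes
only.  Spike regression followed by exclusion of the censored volumes is
algebraically equivalent to deleting them before regression, which a test
asserts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ParcelTimeSeries:
    """parcels x timepoints matrix with TR and a retain-mask."""

    values: np.ndarray
    tr_seconds: float
    censor_mask: np.ndarray | None = None   # True = retain

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be parcels x timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.values.shape[1], dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.size != self.values.shape[1]:
            raise ValueError("censor mask length must match timepoints")
        if int(self.censor_mask.sum()) < 2:
            raise ValueError("need at least 2 retained timepoints")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConfoundSet:
    """timepoints x k nuisance regressors with column labels."""

    columns: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim == 1:
            self.columns = self.columns[:, None]
        if self.columns.size and self.columns.ndim != 2:
            raise ValueError("confounds must be timepoints x k")
        if not self.labels:
            self.labels = [f"confound_{j}" for j in range(self.columns.shape[1] if self.columns.size else 0)]

    @property
    def k(self) -> int:
        return 0 if self.columns.size == 0 else self.columns.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric signed correlation matrix over parcels, zero diagonal."""

    weights: np.ndarray
    node_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric within 1e-12")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(w) > 1.0 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")
        object.__setattr__(self, "weights", w)
        ids = self.node_ids or tuple(f"node_{i}" for i in range(w.shape[0]))
        object.__setattr__(self, "node_ids", tuple(ids))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def censor_by_fd(fd_series: np.ndarray, threshold_mm: float = 0.5) -> np.ndarray:
    """Retain-mask from framewise displacement: volumes with FD strictly
    above the threshold are censored; FD exactly at the threshold is kept."""
    fd = np.asarray(fd_series, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    return fd <= threshold_mm


def dct_highpass_basis(n_timepoints: int, tr_seconds: float, highpass_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis: columns cos(pi*k*(t+0.5)/T) for every
    order k >= 1 whose frequency k/(2*T*TR) is below the cutoff."""
    if highpass_hz <= 0:
        return np.empty((n_timepoints, 0))
    n_basis = int(math.floor(2.0 * n_timepoints * tr_seconds * highpass_hz))
    n_basis = min(n_basis, n_timepoints - 1)
    t = np.arange(n_timepoints)
    cols = [np.cos(np.pi * k * (t + 0.5) / n_timepoints) for k in range(1, n_basis + 1)]
    return np.column_stack(cols) if cols else np.empty((n_timepoints, 0))


def _design_matrix(ts: ParcelTimeSeries, confounds: ConfoundSet | None, highpass_hz: float) -> np.ndarray:
    T = ts.n_timepoints
    parts = [np.ones((T, 1)), (np.arange(T) - (T - 1) / 2.0)[:, None]]
    if confounds is not None and confounds.k:
        if confounds.columns.shape[0] != T:
            raise ValueError("confound rows must match timepoints")
        parts.append(confounds.columns)
    parts.append(dct_highpass_basis(T, ts.tr_seconds, highpass_hz))
    censored = np.flatnonzero(~ts.censor_mask)
    if censored.size:
        spikes = np.zeros((T, censored.size))
        spikes[censored, np.arange(censored.size)] = 1.0
        parts.append(spikes)
    return np.column_stack([p for p in parts if p.size or p.shape[1] == 0])


def nuisance_regress(
    ts: ParcelTimeSeries,
    confounds: ConfoundSet | None = None,
    highpass_hz: float = 0.008,
) -> ParcelTimeSeries:
    """Residualize every parcel series on [trend + confounds + DCT basis +
    censoring spikes] in a single least-squares step.

    Censored timepoints come back exactly zero (their spike column absorbs
    them); retained-timepoint residuals are orthogonal to every regressor.
    """
    X = _design_matrix(ts, confounds, highpass_hz)
    n_retained = int(ts.censor_mask.sum())
    n_nonspike = X.shape[1] - int((~ts.censor_mask).sum())
    if n_nonspike >= n_retained:
        raise ValueError(
            f"rank-deficient design: {n_nonspike} regressors for "
            f"{n_retained} retained timepoints"
        )
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values.T - X @ beta
    resid[~ts.censor_mask, :] = 0.0
    return ParcelTimeSeries(resid.T, ts.tr_seconds, ts.censor_mask.copy())


def correlation_matrix(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation over retained timepoints only; zero diagonal."""
    keep = ts.censor_mask
    if int(keep.sum()) < 3:
        raise ValueError("need at least 3 retained timepoints for correlation")
    data = ts.values[:, keep]
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance parcel(s) over retained timepoints: {dead.tolist()}")
    w = np.corrcoef(data)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w)


def min_run_retention(
    run_masks: list[np.ndarray],
    min_minutes: float = 4.0,
    tr_seconds: float = 0.8,
    min_runs: int = 2,
) -> bool:
    """True iff at least ``min_runs`` runs keep >= ``min_minutes`` of data
    after censoring (retained volumes x TR)."""
    ok = 0
    for mask in run_masks:
        retained_s = float(np.asarray(mask, dtype=bool).sum()) * tr_seconds
        if retained_s >= min_minutes * 60.0:
            ok += 1
    return ok >= min_runs
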