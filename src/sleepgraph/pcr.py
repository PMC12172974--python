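"""Principal-component-regression predictive modeling with
leave-one-site-out cross-validation.

The pipeline, per held-out site: residualize the target on the covariates
(fit on training participants only), standardize the training features,
take their SVD, pick the component count ``k`` by an inner
leave-one-site-out loop over the training sites, regress the residualized
target on the top-``k`` component scores, and predict the held-out site.
``r_cv`` is the Pearson correlation between observed (residualized) and
predicted target pooled over every held-out participant.

Interpretation uses the Haufe transform: the importance of a feature is
its covariance with the model's prediction (equivalently the feature
covariance matrix times the feature-space weight vector), z-scored across
features.  Per-component contributions are the standardized simple
regression coefficients of the residualized target on each component's
scores — components are orthogonal, so these coincide with the
multivariate standardized coefficients and identify the dominant
component.

Every transformation parameter (covariate model, standardization moments,
loadings, ``k``) is estimated on training participants only; nothing from
a held-out site leaks into its own fold's fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: default grid of candidate component counts (capped at the training rank)
DEFAULT_K_GRID: tuple[int, ...] = (10, 25, 50, 75, 100, 150)

_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# covariate handling


def covariate_design(
    pheno,
    columns: Sequence[str] = ("sex", "age", "motion_fd"),
    quadratic: Sequence[str] = ("age", "motion_fd"),
) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate matrix from a phenotype table.

    Categorical columns become indicator columns with the most frequent
    level as the reference; columns listed in ``quadratic`` additionally
    contribute a centered-and-squared term (the age^2 / mean-FD^2 style
    covariates used in covariate-adjusted connectome models).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in columns:
        s = pheno[c]
        if s.dtype == object or str(s.dtype) == "category":
            levels = s.value_counts().index.tolist()
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            v = s.to_numpy(dtype=float)
            cols.append(v)
            names.append(c)
            if c in quadratic:
                cols.append((v - v.mean()) ** 2)
                names.append(f"{c}^2")
    return np.column_stack(cols), names


def _with_intercept(C: np.ndarray | None, n: int) -> np.ndarray:
    if C is None or C.size == 0:
        return np.ones((n, 1))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(len(C)), C])


def residualize(
    target: np.ndarray,
    covariates: np.ndarray | None,
    fit_ids: np.ndarray,
    apply_ids: np.ndarray,
) -> np.ndarray:
    """Covariate residuals for ``apply_ids`` from a least-squares model
    fit on ``fit_ids`` only (no leakage of held-out participants)."""
    y = np.asarray(target, dtype=float)
    D = _with_intercept(covariates, y.size)
    Dfit = D[fit_ids]
    rank = np.linalg.matrix_rank(Dfit)
    if rank < Dfit.shape[1]:
        raise ValueError(
            f"covariate design is rank deficient on the fit set "
            f"(rank {rank} < {Dfit.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(Dfit, y[fit_ids], rcond=None)
    return y[apply_ids] - D[apply_ids] @ beta


def _fast_resid(y: np.ndarray, D: np.ndarray, fit_rows: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Residualize via normal equations (fold sizes are small; D is thin)."""
    Df = D[fit_rows]
    g = Df.T @ Df
    try:
        beta = np.linalg.solve(g, Df.T @ y[fit_rows])
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Df, y[fit_rows], rcond=None)
    return y[rows] - D[rows] @ beta


# ---------------------------------------------------------------------------
# model containers


@dataclass
class PCRModel:
    """Fitted principal-component regression.

    Standardization moments and loadings come from the training set; the
    component regression uses the top ``k`` columns.
    """

    feature_means: np.ndarray
    feature_sds: np.ndarray
    loadings: np.ndarray          # p x k_max orthonormal columns
    singular_values: np.ndarray   # length k_max
    betas: np.ndarray             # length k (regression on component scores)
    intercept: float
    k: int
    n_train: int

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds

    def transform(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        k = self.loadings.shape[1] if k is None else k
        return self.standardize(X) @ self.loadings[:, :k]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X, self.k) @ self.betas + self.intercept

    @property
    def feature_weights(self) -> np.ndarray:
        """Model weights pulled back to standardized feature space."""
        return self.loadings[:, : self.k] @ self.betas


@dataclass(frozen=True)
class ImportanceMap:
    """Haufe-transformed, z-scored per-feature importance."""

    scores: np.ndarray
    feature_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        labels = self.feature_labels or tuple(f"f{i}" for i in range(s.size))
        object.__setattr__(self, "feature_labels", tuple(labels))
        if abs(s.mean()) > 1e-8 or abs(s.std() - 1.0) > 1e-6:
            raise ValueError("importance scores must be z-scored across features")


@dataclass
class CVResult:
    """Pooled out-of-sample predictions from leave-one-site-out CV."""

    predictions: np.ndarray       # NaN where a participant was never held out
    observed: np.ndarray          # residualized target, NaN likewise
    r_cv: float
    per_site_r: dict
    per_site_k: dict

    @property
    def holdout_mask(self) -> np.ndarray:
        return ~np.isnan(self.predictions)


# ---------------------------------------------------------------------------
# fitting


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_pcr(features: np.ndarray, target: np.ndarray, k: int) -> PCRModel:
    """PCA (SVD of the standardized training features) followed by OLS of
    the target on the top-``k`` component scores."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    Xs, mu, sd = _standardize_train(X)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int(np.sum(S > S[0] * _RANK_TOL)) if S.size else 0
    if k < 1 or k > rank:
        raise ValueError(f"k={k} outside valid range 1..{rank} (training rank)")
    scores = U[:, :rank] * S[:rank]
    ybar = float(y.mean())
    betas = (scores[:, :k].T @ (y - ybar)) / (S[:k] ** 2)
    return PCRModel(
        feature_means=mu,
        feature_sds=sd,
        loadings=Vt[:rank].T,
        singular_values=S[:rank],
        betas=betas,
        intercept=ybar,
        k=k,
        n_train=X.shape[0],
    )


def haufe_pattern(model: PCRModel, train_features: np.ndarray) -> np.ndarray:
    """Raw Haufe-transformed pattern: covariance of each standardized
    training feature with the model's prediction.  Identical (a test
    asserts it) to the training feature covariance matrix applied to the
    feature-space weight vector.  Signs are interpretable: positive means
    the feature rises with the predicted target."""
    Xs = model.standardize(train_features)
    Xc = Xs - Xs.mean(axis=0)
    yhat = model.predict(train_features)
    return Xc.T @ (yhat - yhat.mean()) / (len(yhat) - 1)


def haufe_importance(model: PCRModel, train_features: np.ndarray) -> ImportanceMap:
    """Haufe pattern z-scored across features (the exported importance map)."""
    raw = haufe_pattern(model, train_features)
    z = (raw - raw.mean()) / raw.std()
    return ImportanceMap(scores=z)


def component_contributions(
    model: PCRModel, features: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Standardized simple regression coefficient (= correlation) of the
    target on each retained component's scores; the argmax of the absolute
    value is the dominant component."""
    scores = model.transform(features)
    y = np.asarray(target, dtype=float)
    yc = y - y.mean()
    sc = scores - scores.mean(axis=0)
    denom = np.sqrt((sc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, sc.T @ yc / denom, 0.0)
    return out


def dominant_component(model: PCRModel, features: np.ndarray, target: np.ndarray) -> int:
    return int(np.argmax(np.abs(component_contributions(model, features, target))))


# ---------------------------------------------------------------------------
# leave-one-site-out machinery


@dataclass
class _Fold:
    train: np.ndarray
    test: np.ndarray
    site: object
    scores_train: np.ndarray      # centered component scores, n_train x kmax
    svals: np.ndarray
    scores_test: np.ndarray
    ks: list[int]
    inner: list["_InnerFold"] = field(default_factory=list)


@dataclass
class _InnerFold:
    train: np.ndarray             # absolute indices
    val: np.ndarray
    scores_train: np.ndarray
    svals: np.ndarray
    scores_val: np.ndarray
    kmax: int


def _decompose(X: np.ndarray, train: np.ndarray, test: np.ndarray, kmax_wanted: int):
    Xs_tr, mu, sd = _standardize_train(X[train])
    U, S, Vt = np.linalg.svd(Xs_tr, full_matrices=False)
    rank = int(np.sum(S > S[0] * _RANK_TOL)) if S.size else 0
    kmax = min(rank, kmax_wanted)
    V = Vt[:kmax].T
    scores_tr = U[:, :kmax] * S[:kmax]
    scores_te = ((X[test] - mu) / sd) @ V
    return scores_tr, S[:kmax], scores_te, kmax


class LosoPlan:
    """Precomputed per-fold decompositions for leave-one-site-out CV.

    The component scores depend only on the features and the site split,
    so they are computed once; :meth:`evaluate` then runs the full
    target-side pipeline (residualization, nested k selection, component
    regression, held-out prediction) for any target/covariate pair —
    which is what makes recomputing the whole pipeline for thousands of
    permuted targets affordable.
    """

    def __init__(
        self,
        features: np.ndarray,
        site_labels: Sequence,
        k_grid: Sequence[int] = DEFAULT_K_GRID,
        min_site_size: int = 2,
    ) -> None:
        X = np.asarray(features, dtype=float)
        sites = np.asarray(site_labels)
        if X.shape[0] != sites.size:
            raise ValueError("features and site labels must align")
        uniq = list(dict.fromkeys(sites.tolist()))
        if len(uniq) < 3:
            raise ValueError("need at least 3 sites for leave-one-site-out CV")
        if not list(k_grid):
            raise ValueError("empty component-count grid")
        self.n = X.shape[0]
        self.k_grid = sorted(set(int(k) for k in k_grid))
        kmax_wanted = max(self.k_grid)
        self.folds: list[_Fold] = []
        for s in uniq:
            test = np.flatnonzero(sites == s)
            if test.size < min_site_size:
                logger.warning(
                    "site %r has %d participant(s); excluded from holdout", s, test.size
                )
                continue
            train = np.flatnonzero(sites != s)
            sc_tr, sv, sc_te, kmax = _decompose(X, train, test, kmax_wanted)
            ks = [k for k in self.k_grid if k <= kmax] or [kmax]
            fold = _Fold(train, test, s, sc_tr, sv, sc_te, ks)
            if len(ks) > 1:
                train_sites = sites[train]
                for s_in in dict.fromkeys(train_sites.tolist()):
                    val = train[train_sites == s_in]
                    if val.size < min_site_size:
                        continue
                    tr_in = train[train_sites != s_in]
                    sc_i, sv_i, sc_v, kmax_i = _decompose(X, tr_in, val, kmax_wanted)
                    fold.inner.append(_InnerFold(tr_in, val, sc_i, sv_i, sc_v, kmax_i))
            self.folds.append(fold)
        if not self.folds:
            raise ValueError("no site large enough to hold out")

    # -- target-side pipeline -------------------------------------------

    @staticmethod
    def _component_predict(scores_tr, svals, scores_te, y_tr, k):
        ybar = y_tr.mean()
        betas = scores_tr[:, :k].T @ (y_tr - ybar) / (svals[:k] ** 2)
        return scores_te[:, :k] @ betas + ybar

    def _select_k(self, fold: _Fold, y: np.ndarray, D: np.ndarray) -> int:
        if len(fold.ks) == 1 or not fold.inner:
            return fold.ks[0]
        preds = {k: [] for k in fold.ks}
        obs: list[np.ndarray] = []
        for inner in fold.inner:
            y_tr = _fast_resid(y, D, inner.train, inner.train)
            y_val = _fast_resid(y, D, inner.train, inner.val)
            obs.append(y_val)
            for k in fold.ks:
                kk = min(k, inner.kmax)
                preds[k].append(
                    self._component_predict(
                        inner.scores_train, inner.svals, inner.scores_val, y_tr, kk
                    )
                )
        yo = np.concatenate(obs)
        best_k, best_r = fold.ks[0], -np.inf
        for k in fold.ks:               # ascending: ties keep the smaller k
            yp = np.concatenate(preds[k])
            r = _safe_corr(yo, yp)
            if r > best_r + 1e-12:
                best_k, best_r = k, r
        return best_k

    def evaluate(
        self, target: np.ndarray, covariates: np.ndarray | None, global_k: int | None = None
    ) -> CVResult:
        y = np.asarray(target, dtype=float)
        D = _with_intercept(covariates, self.n)
        predictions = np.full(self.n, np.nan)
        observed = np.full(self.n, np.nan)
        per_site_r: dict = {}
        per_site_k: dict = {}
        for fold in self.folds:
            y_tr = _fast_resid(y, D, fold.train, fold.train)
            y_te = _fast_resid(y, D, fold.train, fold.test)
            k = min(global_k, fold.ks[-1]) if global_k else self._select_k(fold, y, D)
            yp = self._component_predict(fold.scores_train, fold.svals, fold.scores_test, y_tr, k)
            predictions[fold.test] = yp
            observed[fold.test] = y_te
            per_site_k[fold.site] = k
            per_site_r[fold.site] = _safe_corr(y_te, yp)
        mask = ~np.isnan(predictions)
        r_cv = _safe_corr(observed[mask], predictions[mask])
        return CVResult(predictions, observed, float(r_cv), per_site_r, per_site_k)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_k_nested(
    train_features: np.ndarray,
    train_target: np.ndarray,
    train_sites: Sequence,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    covariates: np.ndarray | None = None,
) -> int:
    """Component count maximizing the pooled inner leave-one-site-out
    correlation on the training data; ties go to the smaller k."""
    sites = np.asarray(train_sites)
    if len(dict.fromkeys(sites.tolist())) < 3:
        raise ValueError("need at least 3 training sites for nested selection")
    if not list(k_grid):
        raise ValueError("empty component-count grid")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=float)
    ks = sorted(set(int(k) for k in k_grid))
    D = _with_intercept(covariates, len(y))
    preds = {k: [] for k in ks}
    obs: list[np.ndarray] = []
    idx = np.arange(len(y))
    capped = 0
    for s in dict.fromkeys(sites.tolist()):
        val = idx[sites == s]
        tr = idx[sites != s]
        if val.size < 2:
            continue
        sc_tr, sv, sc_val, kmax = _decompose(X, tr, val, max(ks))
        capped = max(capped, kmax)
        y_tr = _fast_resid(y, D, tr, tr)
        y_val = _fast_resid(y, D, tr, val)
        obs.append(y_val)
        for k in ks:
            preds[k].append(
                LosoPlan._component_predict(sc_tr, sv, sc_val, y_tr, min(k, kmax))
            )
    yo = np.concatenate(obs)
    usable = [k for k in ks if k <= capped] or [capped]
    best_k, best_r = usable[0], -np.inf
    for k in usable:
        r = _safe_corr(yo, np.concatenate(preds[k]))
        if r > best_r + 1e-12:
            best_k, best_r = k, r
    return best_k


def loso_cv(
    features: np.ndarray,
    target: np.ndarray,
    covariates: np.ndarray | None,
    site_labels: Sequence,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    global_k: int | None = None,
) -> CVResult:
    """Leave-one-site-out evaluation of the full PCR pipeline.

    Deterministic given the data: there is no internal randomness.
    ``r_cv`` pools all held-out participants rather than averaging
    per-site correlations.
    """
    plan = LosoPlan(features, site_labels, k_grid)
    return plan.evaluate(target, covariates, global_k=global_k)


def stack(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    target: np.ndarray,
    site_labels: Sequence,
) -> CVResult:
    """Second-level stacking of two out-of-sample prediction vectors.

    Under the same LOSO scheme: two-predictor OLS stacking weights are
    fit on the training sites' predictions and applied to the held-out
    site; the pooled correlation is returned.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = np.asarray(target, dtype=float)
    sites = np.asarray(site_labels)
    if not (a.size == b.size == y.size == sites.size):
        raise ValueError("prediction vectors, target and sites must align")
    valid = ~(np.isnan(a) | np.isnan(b) | np.isnan(y))
    predictions = np.full(y.size, np.nan)
    per_site_r: dict = {}
    for s in dict.fromkeys(sites.tolist()):
        test = np.flatnonzero((sites == s) & valid)
        train = np.flatnonzero((sites != s) & valid)
        if test.size < 2 or train.size < 3:
            continue
        D_tr = np.column_stack([np.ones(train.size), a[train], b[train]])
        beta, *_ = np.linalg.lstsq(D_tr, y[train], rcond=None)
        D_te = np.column_stack([np.ones(test.size), a[test], b[test]])
        predictions[test] = D_te @ beta
        per_site_r[s] = _safe_corr(y[test], predictions[test])
    mask = ~np.isnan(predictions)
    r_cv = _safe_corr(y[mask], predictions[mask])
    return CVResult(predictions, np.where(mask, y, np.nan), float(r_cv), per_site_r, {})
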