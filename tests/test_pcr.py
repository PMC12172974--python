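"""PCR fitting, nested selection, LOSO evaluation, Haufe importance."""

import numpy as np
import pytest

from sleepgraph import pcr


@pytest.fixture
def linear_data():
    rng = np.random.default_rng(0)
    n, p = 200, 20
    X = rng.standard_normal((n, p))
    w = rng.standard_normal(p)
    y = X @ w + 0.5 * rng.standard_normal(n)
    return X, y


def test_residualize_basics():
    rng = np.random.default_rng(1)
    n = 100
    C = rng.standard_normal((n, 2))
    ids = np.arange(n)
    # target equal to a covariate column -> residuals ~ 0
    r = pcr.residualize(C[:, 0], C, ids, ids)
    assert np.all(np.abs(r) < 1e-10)
    # covariates orthogonal to target -> residuals = centered target
    y = rng.standard_normal(n)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
    y_orth = y - Q @ (Q.T @ y)
    r2 = pcr.residualize(y_orth, C, ids, ids)
    assert np.allclose(r2, y_orth - y_orth.mean() * 0, atol=1e-10)


def test_residualize_train_only_no_leakage():
    """Fitting the covariate model on train must differ from fitting on
    all data when the held-out site's covariate distribution is shifted."""
    rng = np.random.default_rng(2)
    n = 120
    C = rng.standard_normal((n, 1))
    C[100:] += 5.0                      # shifted held-out site
    y = 2.0 * C[:, 0] + rng.standard_normal(n)
    fit_ids, apply_ids = np.arange(100), np.arange(100, n)
    r_train_fit = pcr.residualize(y, C, fit_ids, apply_ids)
    r_all_fit = pcr.residualize(y, C, np.arange(n), apply_ids)
    assert not np.allclose(r_train_fit, r_all_fit, atol=1e-3)


def test_residualize_rank_deficiency_error():
    rng = np.random.default_rng(3)
    C = rng.standard_normal((50, 2))
    C = np.column_stack([C, C[:, 0]])   # duplicated column
    with pytest.raises(ValueError, match="rank deficient"):
        pcr.residualize(rng.standard_normal(50), C, np.arange(50), np.arange(50))


def test_full_rank_pcr_equals_ols(linear_data):
    X, y = linear_data
    model = pcr.fit_pcr(X, y, k=X.shape[1])
    Xs = model.standardize(X)
    D = np.column_stack([np.ones(len(y)), Xs])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    assert np.allclose(model.predict(X), D @ beta, atol=1e-8)


def test_duplicate_features_leave_predictions_unchanged(linear_data):
    X, y = linear_data
    a = pcr.fit_pcr(X, y, k=5).predict(X)
    b = pcr.fit_pcr(np.hstack([X, X]), y, k=5).predict(np.hstack([X, X]))
    assert np.allclose(a, b, atol=1e-8)


def test_k_out_of_range_errors(linear_data):
    X, y = linear_data
    with pytest.raises(ValueError, match="k="):
        pcr.fit_pcr(X, y, k=X.shape[1] + 1)
    with pytest.raises(ValueError, match="k="):
        pcr.fit_pcr(X, y, k=0)


def test_pca_loadings_match_sklearn(linear_data):
    sklearn_pca = pytest.importorskip("sklearn.decomposition")
    X, y = linear_data
    model = pcr.fit_pcr(X, y, k=5)
    ref = sklearn_pca.PCA(n_components=5).fit((X - X.mean(0)) / X.std(0))
    for j in range(5):
        r = np.corrcoef(model.loadings[:, j], ref.components_[j])[0, 1]
        assert abs(r) > 1 - 1e-8


def test_haufe_closed_forms(linear_data):
    X, y = linear_data
    model = pcr.fit_pcr(X, y, k=10)
    imp = pcr.haufe_importance(model, X)
    # cov(X, yhat) == Cov(X) @ w in standardized space
    Xs = model.standardize(X)
    Xc = Xs - Xs.mean(0)
    cov = Xc.T @ Xc / (len(y) - 1)
    raw_direct = cov @ model.feature_weights
    z_direct = (raw_direct - raw_direct.mean()) / raw_direct.std()
    assert np.allclose(imp.scores, z_direct, atol=1e-8)
    assert abs(imp.scores.mean()) < 1e-8 and abs(imp.scores.std() - 1) < 1e-8


def test_haufe_single_feature_closed_form():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(500)
    X = np.column_stack([x, rng.standard_normal(500)])
    y = 2.0 * (x - x.mean()) / x.std()
    model = pcr.fit_pcr(X, y, k=2)
    Xs = model.standardize(X)
    yhat = model.predict(X)
    raw0 = ((Xs[:, 0] - Xs[:, 0].mean()) * (yhat - yhat.mean())).sum() / (len(y) - 1)
    assert raw0 == pytest.approx(2.0 * Xs[:, 0].var(ddof=1), rel=1e-6)


def test_component_contributions_identify_planted_component(linear_data):
    X, y = linear_data
    model = pcr.fit_pcr(X, y, k=8)
    scores = model.transform(X)
    target = scores[:, 3].copy()
    contrib = pcr.component_contributions(model, X, target)
    assert contrib[3] == pytest.approx(1.0, abs=1e-8)
    assert np.all(np.abs(np.delete(contrib, 3)) < 1e-6)
    # invariant to target scaling
    assert np.allclose(pcr.component_contributions(model, X, 7.5 * target), contrib)
    assert pcr.dominant_component(model, X, target) == 3


def make_sites(n, n_sites, rng):
    return rng.permutation(np.repeat(np.arange(n_sites), n // n_sites))


def test_select_k_trivial_grid(linear_data):
    X, y = linear_data
    sites = make_sites(len(y), 4, np.random.default_rng(5))
    assert pcr.select_k_nested(X, y, sites, k_grid=[3]) == 3


def test_select_k_on_noise_is_deterministic_and_in_grid():
    """With no inner signal the selection carries no information; it must
    still be a deterministic function of the data and land in the grid."""
    rng = np.random.default_rng(6)
    for _ in range(10):
        X = rng.standard_normal((120, 30))
        y = rng.standard_normal(120)
        sites = make_sites(120, 4, rng)
        k = pcr.select_k_nested(X, y, sites, k_grid=[2, 10, 25])
        assert k in (2, 10, 25)
        assert pcr.select_k_nested(X, y, sites, k_grid=[2, 10, 25]) == k


def test_select_k_reaches_planted_component():
    rng = np.random.default_rng(7)
    n, p = 300, 40
    X = rng.standard_normal((n, p))
    U, S, Vt = np.linalg.svd((X - X.mean(0)) / X.std(0), full_matrices=False)
    y = U[:, 7] * S[7] + 0.1 * rng.standard_normal(n)   # signal in component 8
    sites = make_sites(n, 5, rng)
    k = pcr.select_k_nested(X, y, sites, k_grid=[2, 5, 10, 20])
    assert k >= 8


def test_loso_cv_deterministic_and_matches_plan(planted_pipeline):
    d = planted_pipeline
    grid = (5, 10, 20)
    a = pcr.loso_cv(d["X"], d["y"], d["C"], d["sites"], grid)
    b = pcr.loso_cv(d["X"], d["y"], d["C"], d["sites"], grid)
    assert a.r_cv == b.r_cv
    plan = pcr.LosoPlan(d["X"], d["sites"], grid)
    c = plan.evaluate(d["y"], d["C"])
    assert c.r_cv == a.r_cv
    # every participant predicted exactly once
    assert np.all(~np.isnan(a.predictions))
    assert -1 <= a.r_cv <= 1


def test_loso_cv_recovers_planted_signal(planted_pipeline):
    d = planted_pipeline
    cv = pcr.loso_cv(d["X"], d["y"], d["C"], d["sites"], (5, 10, 20))
    assert cv.r_cv > 0.3


def test_loso_cv_null_is_small():
    from conftest import small_spec
    from sleepgraph import factor, graph, synthetic

    rs = []
    for seed in range(3):
        coh = synthetic.generate_null_cohort(small_spec(seed=100 + seed))
        X = graph.build_feature_matrix([m.weights for m in coh.connectomes], coh.communities)
        ph, _ = factor.add_sleep_scores(coh.phenotypes)
        C, _ = pcr.covariate_design(ph)
        cv = pcr.loso_cv(X, ph["sleep_deficit"].to_numpy(), C, ph["site"], (5, 10))
        rs.append(cv.r_cv)
    assert abs(np.mean(rs)) < 0.25


def test_stack_degenerate_and_noise_cases(planted_pipeline):
    d = planted_pipeline
    cv = pcr.loso_cv(d["X"], d["y"], d["C"], d["sites"], (5, 10, 20))
    obs = cv.observed
    # identical predictors collapse to the single-predictor second-level
    # model (a zero second column is the explicit single-predictor case)
    st_same = pcr.stack(cv.predictions, cv.predictions, obs, d["sites"])
    st_single = pcr.stack(cv.predictions, np.zeros_like(obs), obs, d["sites"])
    assert st_same.r_cv == pytest.approx(st_single.r_cv, abs=1e-8)
    with pytest.raises(ValueError, match="align"):
        pcr.stack(cv.predictions[:-1], cv.predictions[:-1], obs, d["sites"])


def test_stack_with_pure_noise_predictor_matches_single_model():
    rng = np.random.default_rng(8)
    diffs = []
    for _ in range(10):
        n = 600
        sites = make_sites(n, 6, rng)
        truth = rng.standard_normal(n)
        a = truth + 1.5 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        st_a = pcr.stack(a, a, truth, sites)          # baseline: a alone
        st_n = pcr.stack(a, noise, truth, sites)
        diffs.append(st_n.r_cv - st_a.r_cv)
    assert abs(np.mean(diffs)) < 0.02


def test_stack_combines_independent_signal_halves():
    rng = np.random.default_rng(9)
    n = 600
    sites = make_sites(n, 6, rng)
    truth = rng.standard_normal(n)
    a = truth + 1.4 * rng.standard_normal(n)
    b = truth + 1.4 * rng.standard_normal(n)
    st = pcr.stack(a, b, truth, sites)
    r_a = np.corrcoef(a, truth)[0, 1]
    r_b = np.corrcoef(b, truth)[0, 1]
    assert st.r_cv > max(r_a, r_b)


def test_covariate_design_dummies_and_quadratics(planted_pipeline):
    pheno = planted_pipeline["pheno"]
    C, names = pcr.covariate_design(pheno, ("sex", "age", "motion_fd"))
    assert "age^2" in names and "motion_fd^2" in names
    assert C.shape[0] == len(pheno)
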