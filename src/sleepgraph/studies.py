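"""Reference study designs run on the synthetic generator.

These functions wire the pipeline stages together under fixed study
conditions — planted-signal recovery across seeds, type-I error of the
block-permutation test on null cohorts, and split-half component
transport — and are used both by the test suite and by the results
reproduction script.  Problem sizes are desk-scale: cohorts of a few
hundred participants with 24-60 nodes, which the generator's noise
levels were chosen for.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import components, factor, pcr, permutation, synthetic
from .graph import build_feature_matrix

RECOVERY_K_GRID = (5, 10, 20, 40)
NULL_K_GRID = (5, 10)


def prepare(cohort: synthetic.SyntheticCohort):
    """Features, scored phenotypes, target and covariates for a cohort."""
    X = build_feature_matrix([m.weights for m in cohort.connectomes], cohort.communities)
    pheno, fmodel = factor.add_sleep_scores(cohort.phenotypes)
    y = pheno["sleep_deficit"].to_numpy(dtype=float)
    C, _ = pcr.covariate_design(pheno)
    return X, pheno, y, C, fmodel


def fit_full_model(X, y, C, k: int) -> tuple[pcr.PCRModel, np.ndarray]:
    """Final interpretation model: residualize the target on the full
    sample, PCR at component count ``k`` (capped at the rank)."""
    ids = np.arange(len(y))
    y_res = pcr.residualize(y, C, ids, ids)
    kmax = min(k, np.linalg.matrix_rank(X - X.mean(0)))
    return pcr.fit_pcr(X, y_res, kmax), y_res


def planted_seed_run(
    spec: synthetic.CohortSpec, B: int = 199, perm_seed: int = 0,
    k_grid=RECOVERY_K_GRID,
) -> dict:
    """One planted cohort through the whole pipeline.

    Returns the pooled LOSO r_cv, its block-permutation p-value, the
    sign-aligned correlation of the dominant component with the planted
    truth direction, and the fraction of target-network nodes whose raw
    Haufe pattern shows the planted motif (positive MDP, negative PCP).
    """
    cohort = synthetic.generate_cohort(spec)
    X, pheno, y, C, _ = prepare(cohort)
    sites = pheno["site"].to_numpy()

    cv = pcr.loso_cv(X, y, C, sites, k_grid)
    perm = permutation.permutation_test(
        X, y, C, cohort.blocks, sites, B=B, seed=perm_seed, k_grid=k_grid
    )

    model, y_res = fit_full_model(X, y, C, k=max(k_grid))
    dom = pcr.dominant_component(model, X, y_res)
    comp = components.from_pcr_model(model, dom, cohort.truth.feature_labels)
    truth_r = float(np.corrcoef(comp.coefficients, cohort.truth.loadings)[0, 1])

    pattern = pcr.haufe_pattern(model, X)
    n = spec.n_nodes
    tn = cohort.truth.target_nodes
    mdp_ok = pattern[tn] > 0
    pcp_ok = pattern[n + tn] < 0
    sign_fraction = float(np.mean(mdp_ok & pcp_ok))

    return {
        "r_cv": cv.r_cv,
        "p_value": perm.p_value,
        "dominant_component": dom,
        "truth_correlation_aligned": abs(truth_r),
        "target_sign_fraction": sign_fraction,
        "cohort": cohort,
        "model": model,
        "per_site_k": cv.per_site_k,
    }


def recovery_study(
    n_seeds: int = 20, base_seed: int = 0, B: int = 199,
    spec: synthetic.CohortSpec | None = None,
) -> dict:
    """Planted-signal recovery across generator seeds."""
    spec = spec or synthetic.CohortSpec()
    runs = [
        planted_seed_run(replace(spec, seed=base_seed + i), B=B, perm_seed=base_seed + i)
        for i in range(n_seeds)
    ]
    return {
        "r_cv": np.array([r["r_cv"] for r in runs]),
        "p_values": np.array([r["p_value"] for r in runs]),
        "truth_correlations": np.array([r["truth_correlation_aligned"] for r in runs]),
        "sign_fractions": np.array([r["target_sign_fraction"] for r in runs]),
    }


def type_i_error_study(
    n_replicates: int = 200, B: int = 199, base_seed: int = 0,
    spec: synthetic.CohortSpec | None = None, alpha: float = 0.05,
) -> dict:
    """Permutation p-values over null cohorts (no planted effect)."""
    spec = spec or synthetic.CohortSpec(
        n_participants=150, n_sites=5, n_nodes=30, community_sizes=(10, 10, 10)
    )
    p_values = np.empty(n_replicates)
    for i in range(n_replicates):
        cohort = synthetic.generate_null_cohort(replace(spec, seed=base_seed + i))
        X, pheno, y, C, _ = prepare(cohort)
        res = permutation.permutation_test(
            X, y, C, cohort.blocks, pheno["site"].to_numpy(),
            B=B, seed=base_seed + i, k_grid=NULL_K_GRID,
        )
        p_values[i] = res.p_value
    return {
        "p_values": p_values,
        "rejection_rate": float(np.mean(p_values <= alpha)),
        "alpha": alpha,
    }


def split_half_transport(
    seed: int = 0, spec: synthetic.CohortSpec | None = None, k: int = 40
) -> dict:
    """Derive the dominant component independently in two halves of a
    planted cohort (split within site), compare loadings, and project the
    first half's component onto the second half."""
    spec = spec or synthetic.CohortSpec()
    cohort = synthetic.generate_cohort(replace(spec, seed=seed))
    X, pheno, y, C, _ = prepare(cohort)
    rng = np.random.default_rng(seed)
    half_a = np.zeros(len(y), dtype=bool)
    for s in pheno["site"].unique():
        idx = np.flatnonzero(pheno["site"].to_numpy() == s)
        half_a[rng.permutation(idx)[: idx.size // 2]] = True

    comps, models, doms = [], [], []
    for mask in (half_a, ~half_a):
        model, y_res = fit_full_model(X[mask], y[mask], C[mask], k)
        dom = pcr.dominant_component(model, X[mask], y_res)
        comps.append(components.from_pcr_model(model, dom, cohort.truth.feature_labels))
        models.append(model)
        doms.append(dom)

    sim = components.loading_similarity(comps[0], comps[1])
    # transport: half-A component applied to half-B participants
    proj_ab = components.project(X[~half_a], comps[0])
    own_b = components.project(X[~half_a], comps[1])
    proj_r = abs(float(np.corrcoef(proj_ab, own_b)[0, 1]))
    return {
        "loading_similarity_aligned": sim.sign_aligned,
        "loading_similarity_signed": sim.signed,
        "projection_correlation": proj_r,
        "dominant_components": tuple(doms),
    }
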