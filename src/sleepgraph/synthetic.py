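"""Synthetic multi-site, family-nested connectome cohorts with a planted
"network disconnection" motif.

The generator emulates the structure of a large multi-site developmental
cohort at connectome level (it makes no attempt at fMRI time-series
realism).  Each participant gets:

* a community-structured correlation-like matrix (higher mean weight
  within than between networks), perturbed along a fixed motif — edges
  within one target network strengthen while edges from that network to
  the rest weaken — in proportion to ``effect_size`` times the
  participant's latent trait, plus a site-specific shift and edge noise;
* three noisy sleep-duration indicators (hours) loading on the latent
  trait with distinct loadings and noise levels;
* covariates (sex, age, motion) that leak into the latent trait and the
  connectome noise level, so naive analyses are confounded the way real
  cohorts are;
* context/outcome phenotypes that are linear in the latent trait.

Sign convention: a larger latent value means *shorter* sleep, so the
planted motif is a signature of sleep deficit.  The ground-truth loading
direction of the motif over the 2n graph features is computed as the
numerical derivative of the feature map at the base matrix and returned
unit-normalized, enabling exact recovery checks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .graph import CommunityAssignment, build_feature_vector, feature_labels
from .permutation import ExchangeabilityBlocks

#: default slopes of context/outcome phenotypes on the standardized latent
#: sleep-deficit trait (positive latent = shorter sleep)
DEFAULT_OUTCOME_EFFECTS: dict[str, float] = {
    "income": -0.20,
    "education": -0.15,
    "adi": 0.15,
    "screen_time": 0.30,
    "ext_youth": 0.20,
    "ext_parent": 0.20,
    "int_youth": 0.05,
    "int_parent": 0.00,
    "grades": -0.15,
    "cognition": -0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_participants: int = 600
    n_sites: int = 6
    family_size_probs: tuple[float, float, float] = (0.55, 0.35, 0.10)  # sizes 1,2,3
    n_nodes: int = 60
    community_sizes: tuple[int, ...] = (10, 10, 10, 10, 10, 10)
    target_network: str = "net0"
    effect_size: float = 0.5
    indicator_loadings: tuple[float, float, float] = (0.8, 0.7, 0.6)
    indicator_noise_sd: tuple[float, float, float] = (0.60, 0.71, 0.80)
    covariate_latent_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.10, "sex": 0.10, "motion": 0.20}
    )
    motion_noise_effect: float = 0.30
    edge_noise_sd: float = 0.06
    site_shift_sd: float = 0.02
    within_base: float = 0.35
    between_base: float = 0.10
    motif_edge_scale: float = 0.03
    outcome_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError("community_sizes must sum to n_nodes")
        if any(s < 2 for s in self.community_sizes):
            raise ValueError("every community needs at least 2 nodes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if any(not (0 < lo <= 1) for lo in self.indicator_loadings):
            raise ValueError("indicator loadings must lie in (0, 1]")
        if any(sd <= 0 for sd in self.indicator_noise_sd):
            raise ValueError("indicator noise sds must be positive")
        if self.n_participants < self.n_sites:
            raise ValueError("n_participants must be >= n_sites")
        if self.target_network not in self.network_labels():
            raise ValueError(
                f"target network {self.target_network!r} not among {self.network_labels()}"
            )
        p = np.asarray(self.family_size_probs, dtype=float)
        if p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ValueError("family_size_probs must be a distribution over sizes 1..3")

    def network_labels(self) -> tuple[str, ...]:
        return tuple(f"net{i}" for i in range(len(self.community_sizes)))

    def communities(self) -> CommunityAssignment:
        labels: list[str] = []
        for lab, size in zip(self.network_labels(), self.community_sizes):
            labels.extend([lab] * size)
        return CommunityAssignment(tuple(labels), self.network_labels())


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of the planted signal.

    ``loadings`` is the unit-norm motif direction over the 2n graph
    features expressed in *standardized* feature space (each raw gradient
    entry divided by that feature's cohort standard deviation) — the
    space PCA components of standardized features live in, so recovered
    components are directly comparable.  ``raw_gradient`` keeps the
    unit-norm derivative of the feature map in raw feature units.
    """

    loadings: np.ndarray
    raw_gradient: np.ndarray
    latent: np.ndarray            # per-participant sleep-deficit trait (standardized)
    feature_labels: tuple[str, ...]
    target_nodes: np.ndarray      # node indices of the disconnected network


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    connectomes: list[ConnectivityMatrix]
    phenotypes: pd.DataFrame
    communities: CommunityAssignment
    blocks: ExchangeabilityBlocks
    truth: CohortTruth

    def __post_init__(self) -> None:
        if len(self.connectomes) != len(self.phenotypes):
            raise ValueError("one connectome per phenotype row required")


def _motif_matrix(spec: CohortSpec) -> np.ndarray:
    """+1 on edges within the target network, -1 on edges from it to the
    rest, 0 elsewhere; zero diagonal."""
    comm = spec.communities()
    in_target = np.zeros(spec.n_nodes, dtype=bool)
    in_target[comm.indices_of(spec.target_network)] = True
    d = np.zeros((spec.n_nodes, spec.n_nodes))
    d[np.ix_(in_target, in_target)] = 1.0
    d[np.ix_(in_target, ~in_target)] = -1.0
    d[np.ix_(~in_target, in_target)] = -1.0
    np.fill_diagonal(d, 0.0)
    return d


def _base_matrix(spec: CohortSpec) -> np.ndarray:
    comm = spec.communities()
    h = comm.membership_matrix()
    same = h @ h.T
    b = np.where(same > 0, spec.within_base, spec.between_base)
    np.fill_diagonal(b, 0.0)
    return b


def truth_loadings(spec: CohortSpec, eps: float = 1e-4) -> np.ndarray:
    """Unit-norm derivative of the graph-feature map along the planted
    motif, evaluated at the noise-free base matrix (central differences)."""
    comm = spec.communities()
    base = _base_matrix(spec)
    step = eps * _motif_matrix(spec)
    f_plus = build_feature_vector(np.clip(base + step, -1, 1), comm).values
    f_minus = build_feature_vector(np.clip(base - step, -1, 1), comm).values
    grad = (f_plus - f_minus) / (2 * eps)
    norm = np.linalg.norm(grad)
    if norm == 0:
        raise ValueError("degenerate motif: zero feature gradient")
    return grad / norm


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    z = rng.normal(0.0, sd, size=(n, n))
    z = (z + z.T) / np.sqrt(2.0)
    np.fill_diagonal(z, 0.0)
    return z


def _make_families(spec: CohortSpec, rng: np.random.Generator):
    """Family sizes drawn i.i.d. from family_size_probs, last family
    truncated to hit n_participants; families assigned whole to the
    currently least-filled site (so sizes stay within one family of even)."""
    sizes: list[int] = []
    total = 0
    while total < spec.n_participants:
        s = int(rng.choice([1, 2, 3], p=np.asarray(spec.family_size_probs)))
        s = min(s, spec.n_participants - total)
        sizes.append(s)
        total += s
    site_fill = np.zeros(spec.n_sites, dtype=int)
    # seed every site with one family first so no site is empty
    site_of_family: list[int] = []
    for j, s in enumerate(sizes):
        if j < spec.n_sites:
            site = j
        else:
            site = int(np.argmin(site_fill))
        site_of_family.append(site)
        site_fill[site] += s
    site_of = np.repeat(site_of_family, sizes)
    family_of = np.repeat(np.arange(len(sizes)), sizes)
    return site_of, family_of


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort.  Identical spec (including seed) reproduces the
    cohort bit-for-bit; per-participant noise comes from spawned
    substreams keyed by participant index, so the draw for participant i
    does not depend on how many participants follow it."""
    root = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    n = spec.n_participants
    comm = spec.communities()

    site_of, family_of = _make_families(spec, cohort_rng)
    order = np.argsort(site_of, kind="stable")
    site_of, family_of = site_of[order], family_of[order]

    # covariates
    age = cohort_rng.uniform(11.0, 13.0, size=n)
    sex = cohort_rng.integers(0, 2, size=n)
    motion = np.exp(cohort_rng.normal(np.log(0.2), 0.4, size=n))

    z_age = (age - 12.0) / np.sqrt(1.0 / 3.0)
    z_sex = (sex - 0.5) * 2.0
    z_motion = (np.log(motion) - np.log(0.2)) / 0.4

    eff = spec.covariate_latent_effects
    raw_latent = (
        cohort_rng.standard_normal(n)
        + eff.get("age", 0.0) * z_age
        + eff.get("sex", 0.0) * z_sex
        + eff.get("motion", 0.0) * z_motion
    )
    latent = (raw_latent - raw_latent.mean()) / raw_latent.std()

    base = _base_matrix(spec)
    motif = _motif_matrix(spec)
    site_shifts = []
    for s in range(spec.n_sites):
        srng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1, s)))
        site_shifts.append(_symmetric_noise(srng, spec.n_nodes, spec.site_shift_sd))

    connectomes: list[ConnectivityMatrix] = []
    node_ids = tuple(f"node_{i}" for i in range(spec.n_nodes))
    for i in range(n):
        prng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2, i)))
        noise_sd = spec.edge_noise_sd * max(0.2, 1.0 + spec.motion_noise_effect * z_motion[i])
        w = (
            base
            + spec.effect_size * latent[i] * spec.motif_edge_scale * motif
            + site_shifts[site_of[i]]
            + _symmetric_noise(prng, spec.n_nodes, noise_sd)
        )
        w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(w, 0.0)
        connectomes.append(ConnectivityMatrix(w, node_ids))

    # sleep indicators in hours: larger latent = shorter sleep
    lam = spec.indicator_loadings
    nsd = spec.indicator_noise_sd
    centers = (9.2, 8.8, 7.4)      # parent-report, youth-report, fitbit
    hours_scale = 0.8
    sleep_cols = {}
    for j, name in enumerate(["sleep_parent", "sleep_youth", "sleep_fitbit"]):
        std_indicator = lam[j] * latent + cohort_rng.normal(0.0, nsd[j], size=n)
        sleep_cols[name] = centers[j] - hours_scale * std_indicator

    pheno = pd.DataFrame(
        {
            "id": [f"sub-{i:05d}" for i in range(n)],
            "site": [f"site{site_of[i]:02d}" for i in range(n)],
            "family": [f"fam{family_of[i]:05d}" for i in range(n)],
            **sleep_cols,
            "sex": sex,
            "age": age,
            "motion_fd": motion,
        }
    )
    for name, slope in spec.outcome_effects.items():
        pheno[name] = slope * latent + cohort_rng.standard_normal(n) * np.sqrt(
            max(1.0 - slope**2, 0.1)
        )

    blocks = ExchangeabilityBlocks(
        site_of=tuple(pheno["site"]), family_of=tuple(pheno["family"])
    )
    raw_grad = truth_loadings(spec)
    feats = np.vstack([build_feature_vector(m.weights, comm).values for m in connectomes])
    feat_sd = feats.std(axis=0)
    feat_sd = np.where(feat_sd == 0, 1.0, feat_sd)
    std_loadings = raw_grad / feat_sd
    std_loadings = std_loadings / np.linalg.norm(std_loadings)
    truth = CohortTruth(
        loadings=std_loadings,
        raw_gradient=raw_grad,
        latent=latent,
        feature_labels=tuple(feature_labels(spec.n_nodes)),
        target_nodes=comm.indices_of(spec.target_network),
    )
    return SyntheticCohort(spec, connectomes, pheno, comm, blocks, truth)


def generate_null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Same cohort machinery with the motif coupling forced to zero; the
    truth loadings are still returned for interface uniformity."""
    return generate_cohort(replace(spec, effect_size=0.0))
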