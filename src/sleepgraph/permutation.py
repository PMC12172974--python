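"""Block-restricted permutation inference for the LOSO-CV correlation.

Participants are nested in families, families in acquisition sites.
Under the permutation null only relabelings that respect that structure
are admissible: individuals shuffle within their family, whole families
of identical size exchange within their site, and nobody ever crosses a
site boundary.  The target (together with its covariate rows, so the
covariate-target coupling is preserved under the null) is permuted and
the entire predictive pipeline — covariate residualization, nested
component-count selection, PCR fit, leave-one-site-out evaluation — is
recomputed for every draw.  The p-value uses the add-one rule
``(1 + #{null >= observed}) / (1 + B)`` and is one-sided: the alternative
is positive out-of-sample predictivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import pcr as _pcr

__all__ = [
    "ExchangeabilityBlocks",
    "PermutationResult",
    "block_permutation",
    "permutation_test",
]


@dataclass(frozen=True)
class ExchangeabilityBlocks:
    """Per-participant site and family identifiers; families never span sites."""

    site_of: tuple
    family_of: tuple

    def __post_init__(self) -> None:
        site = tuple(self.site_of)
        fam = tuple(self.family_of)
        if len(site) != len(fam):
            raise ValueError("site_of and family_of must have equal length")
        object.__setattr__(self, "site_of", site)
        object.__setattr__(self, "family_of", fam)
        fam_site: dict = {}
        for s, f in zip(site, fam):
            if f in fam_site and fam_site[f] != s:
                raise ValueError(f"family {f!r} spans sites {fam_site[f]!r} and {s!r}")
            fam_site[f] = s

    @property
    def n(self) -> int:
        return len(self.site_of)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float

    @property
    def n_permutations(self) -> int:
        return int(np.asarray(self.null_values).size)


def block_permutation(blocks: ExchangeabilityBlocks, rng) -> np.ndarray:
    """One admissible participant relabeling.

    Returns an index array ``perm`` (a bijection on ``0..n-1``) meant to
    be applied as ``y[perm]``: within every site, families of the same
    size are exchanged as whole blocks uniformly at random and members
    are shuffled within each family.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    site = np.asarray(blocks.site_of, dtype=object)
    fam = np.asarray(blocks.family_of, dtype=object)
    perm = np.arange(blocks.n)
    for s in dict.fromkeys(site.tolist()):
        in_site = np.flatnonzero(site == s)
        groups: dict[int, list[np.ndarray]] = {}
        for f in dict.fromkeys(fam[in_site].tolist()):
            members = in_site[fam[in_site] == f]
            groups.setdefault(members.size, []).append(members)
        for size, fams in groups.items():
            order = rng.permutation(len(fams))
            for slot_i, src_i in enumerate(order):
                src = fams[src_i]
                if size > 1:
                    src = src[rng.permutation(size)]
                perm[fams[slot_i]] = src
    return perm


def permutation_test(
    features: np.ndarray,
    target: np.ndarray,
    covariates: np.ndarray | None,
    blocks: ExchangeabilityBlocks,
    site_labels: Sequence | None = None,
    B: int = 2000,
    seed: int = 0,
    k_grid: Sequence[int] = _pcr.DEFAULT_K_GRID,
) -> PermutationResult:
    """Significance of the pooled LOSO-CV correlation under the block null.

    Component loadings and standardization depend on the features only,
    so the per-fold decompositions are computed once and reused across
    permutations; each draw still re-runs residualization, nested k
    selection, the component regression, and the held-out evaluation.
    """
    if B < 99:
        raise ValueError("B must be >= 99 for usable p-value resolution")
    y = np.asarray(target, dtype=float)
    if site_labels is None:
        site_labels = blocks.site_of
    if y.size != blocks.n:
        raise ValueError("target length must match block structure")
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    plan = _pcr.LosoPlan(np.asarray(features, dtype=float), site_labels, k_grid)
    observed = plan.evaluate(y, C).r_cv
    rng = np.random.default_rng(seed)
    nulls = np.empty(B)
    for b in range(B):
        perm = block_permutation(blocks, rng)
        Cp = None if C is None else C[perm]
        nulls[b] = plan.evaluate(y[perm], Cp).r_cv
    p = (1.0 + np.sum(nulls >= observed)) / (1.0 + B)
    return PermutationResult(observed=float(observed), null_values=nulls, p_value=float(p))
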