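"""Nodewise segregation/integration features on weighted brain graphs.

Two metrics per node, computed on the positive-thresholded weighted graph
with communities fixed by the parcellation:

* **MDP** — within-module degree for positive edges: the summed positive
  edge weight from a node to the other members of its own network.  Unlike
  the classical module-degree z score, no within-network z-scoring is
  applied, so the value tracks differences between participants rather
  than between nodes.
* **PCP** — participation coefficient for positive edges:
  ``1 - sum_s (kappa_is / k_i)**2`` over networks *s*, where ``kappa_is``
  is the positive strength from node *i* into network *s* and ``k_i`` its
  total positive strength.  Values lie in ``[0, 1 - 1/M]`` for *M*
  networks; an isolated node (zero positive strength) is assigned 0.

The feature vector for a participant is all MDP values for nodes
``0..n-1`` followed by all PCP values (length ``2n``); this ordering is
versioned (``FEATURE_ORDER_VERSION``) so fitted models and importance
maps remain portable across files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FEATURE_ORDER_VERSION = "mdp-then-pcp-v1"

__all__ = [
    "CommunityAssignment",
    "GraphFeatureVector",
    "positive_part",
    "within_module_degree_positive",
    "participation_coefficient_positive",
    "build_feature_vector",
    "feature_labels",
    "vectorize_edges",
    "unvectorize_edges",
    "FEATURE_ORDER_VERSION",
]


@dataclass(frozen=True)
class CommunityAssignment:
    """Node -> network labelling with a fixed network order."""

    node_to_network: tuple[str, ...]
    networks: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.node_to_network)
        object.__setattr__(self, "node_to_network", labels)
        nets = tuple(self.networks) if self.networks else tuple(dict.fromkeys(labels))
        object.__setattr__(self, "networks", nets)
        if len(nets) < 2:
            raise ValueError("community assignment needs at least 2 networks")
        missing = set(labels) - set(nets)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in network list")
        counts = {n: labels.count(n) for n in nets}
        empty = [n for n, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"empty networks: {empty}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_to_network)

    def membership_matrix(self) -> np.ndarray:
        """n_nodes x M one-hot indicator of network membership."""
        idx = {n: j for j, n in enumerate(self.networks)}
        out = np.zeros((self.n_nodes, len(self.networks)))
        for i, lab in enumerate(self.node_to_network):
            out[i, idx[lab]] = 1.0
        return out

    def indices_of(self, network: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.node_to_network) == network)


@dataclass(frozen=True)
class GraphFeatureVector:
    """Per-node MDP then per-node PCP, concatenated (length 2n)."""

    mdp: np.ndarray
    pcp: np.ndarray

    def __post_init__(self) -> None:
        mdp = np.asarray(self.mdp, dtype=float)
        pcp = np.asarray(self.pcp, dtype=float)
        if mdp.shape != pcp.shape or mdp.ndim != 1:
            raise ValueError("mdp and pcp must be 1-d arrays of equal length")
        if np.any(mdp < -1e-12):
            raise ValueError("MDP must be nonnegative")
        object.__setattr__(self, "mdp", mdp)
        object.__setattr__(self, "pcp", pcp)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.mdp, self.pcp])

    @property
    def n_nodes(self) -> int:
        return self.mdp.size

    def labels(self) -> list[str]:
        return feature_labels(self.n_nodes)


def feature_labels(n_nodes: int) -> list[str]:
    return [f"mdp_{i}" for i in range(n_nodes)] + [f"pcp_{i}" for i in range(n_nodes)]


def _as_weight_matrix(m) -> np.ndarray:
    w = m.weights if hasattr(m, "weights") else np.asarray(m, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity matrix must be square")
    return w


def positive_part(m) -> np.ndarray:
    """Zero out negative edges; the nonnegative part is returned unchanged.

    Idempotent; symmetry and the zero diagonal are preserved.
    """
    w = _as_weight_matrix(m).copy()
    w[w < 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def _check_nodes(w: np.ndarray, c: CommunityAssignment) -> None:
    if w.shape[0] != c.n_nodes:
        raise ValueError(
            f"matrix has {w.shape[0]} nodes but community table has {c.n_nodes}"
        )


def within_module_degree_positive(m, c: CommunityAssignment) -> np.ndarray:
    """MDP: summed positive weight from each node to its own network.

    The input is expected to be positive-thresholded already (as done by
    :func:`build_feature_vector`); weights are used as given.
    """
    w = _as_weight_matrix(m)
    _check_nodes(w, c)
    h = c.membership_matrix()          # n x M
    per_net = w @ h                    # strength into each network
    own = (h > 0)
    return per_net[own]


def participation_coefficient_positive(m, c: CommunityAssignment) -> np.ndarray:
    """PCP: 1 - sum over networks of the squared strength fraction.

    Nodes with zero total positive strength get 0 (the 0/0 convention
    used by the common graph toolboxes).
    """
    w = _as_weight_matrix(m)
    _check_nodes(w, c)
    h = c.membership_matrix()
    kappa = w @ h                      # n x M
    k = kappa.sum(axis=1)
    out = np.zeros(w.shape[0])
    nz = k > 0
    frac = kappa[nz] / k[nz, None]
    out[nz] = 1.0 - np.sum(frac * frac, axis=1)
    return out


def build_feature_vector(m, c: CommunityAssignment) -> GraphFeatureVector:
    """Positive-threshold once, then compute MDP and PCP for every node."""
    w = positive_part(m)
    return GraphFeatureVector(
        mdp=within_module_degree_positive(w, c),
        pcp=participation_coefficient_positive(w, c),
    )


def build_feature_matrix(matrices: Sequence, c: CommunityAssignment) -> np.ndarray:
    """Stack per-participant feature vectors into an (n_participants, 2n) array."""
    return np.vstack([build_feature_vector(m, c).values for m in matrices])


def vectorize_edges(m) -> np.ndarray:
    """Strict upper triangle in row-major order (length n(n-1)/2).

    Signed values are retained; the full-connectome predictive model uses
    the signed edge weights directly.
    """
    w = _as_weight_matrix(m)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


def unvectorize_edges(v: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; returns a symmetric zero-diagonal matrix."""
    v = np.asarray(v, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if v.size != expected:
        raise ValueError(f"edge vector length {v.size} != {expected} for n={n_nodes}")
    w = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    w[iu] = v
    return w + w.T
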