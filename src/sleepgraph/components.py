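"""PCA components as portable measurement instruments.

A component derived in one sample (its loading vector plus the deriving
sample's feature standardization) can be applied to an independent
sample: standardize the new features with the *deriving* sample's moments
and take the dot product with the loading vector.  Using the deriving
moments keeps the component a fixed instrument rather than re-estimating
it.  Because the sign of a PCA component is arbitrary, loadings are
oriented so their largest-magnitude coefficient is positive, and
cross-sample similarity is reported both signed and sign-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pcr import PCRModel


@dataclass(frozen=True)
class ComponentLoadings:
    """One PCA component with its deriving-sample standardization."""

    coefficients: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    feature_labels: tuple[str, ...]
    label: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        norm = np.linalg.norm(c)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError(f"coefficients must have unit norm (got {norm:.6f})")
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        labels = self.feature_labels or tuple(f"f{i}" for i in range(c.size))
        object.__setattr__(self, "feature_labels", tuple(labels))


def orient(coefficients: np.ndarray) -> np.ndarray:
    """Fix the arbitrary PCA sign: largest-magnitude coefficient positive."""
    c = np.asarray(coefficients, dtype=float)
    return -c if c[np.argmax(np.abs(c))] < 0 else c


def from_pcr_model(
    model: PCRModel, component: int, feature_labels=()
) -> ComponentLoadings:
    """Extract one oriented component (and the training standardization)
    from a fitted PCR model."""
    if not (0 <= component < model.loadings.shape[1]):
        raise ValueError(f"component {component} outside 0..{model.loadings.shape[1]-1}")
    return ComponentLoadings(
        coefficients=orient(model.loadings[:, component]),
        means=model.feature_means,
        sds=model.feature_sds,
        feature_labels=tuple(feature_labels),
        label=component,
    )


def project(features: np.ndarray, comp: ComponentLoadings, feature_labels=None) -> np.ndarray:
    """Component expression scores for a new sample: standardize with the
    deriving sample's moments, then a vector dot product."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != comp.coefficients.size:
        raise ValueError(
            f"feature count {X.shape[1]} != component length {comp.coefficients.size}"
        )
    if feature_labels is not None and tuple(feature_labels) != comp.feature_labels:
        raise ValueError("feature labels do not match the component's ordering")
    return ((X - comp.means) / comp.sds) @ comp.coefficients


@dataclass(frozen=True)
class LoadingSimilarity:
    signed: float
    sign_aligned: float


def loading_similarity(a: ComponentLoadings, b: ComponentLoadings) -> LoadingSimilarity:
    """Pearson correlation of two components' coefficient vectors, signed
    and in absolute value (PCA signs are arbitrary)."""
    if a.coefficients.size != b.coefficients.size:
        raise ValueError("components have different lengths")
    r = float(np.corrcoef(a.coefficients, b.coefficients)[0, 1])
    return LoadingSimilarity(signed=r, sign_aligned=abs(r))
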