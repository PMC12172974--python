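"""Plain-text readers and writers for the pipeline's file formats.

Formats (all diff-able text):

* connectome: dense numeric TSV, n_nodes rows x n_nodes columns, no header
* community table: TSV with columns node_index (0-based), network_label
* phenotypes: CSV with id/site/family, sleep indicators, covariates, outcomes
* feature matrix: CSV, one row per participant, header ``id,mdp_0,...``
  preceded by a comment line recording the feature-ordering version
* component loadings: CSV with feature_label, coefficient, mean, sd
* parcel time series: TSV, parcels x timepoints, no header
* confounds: TSV with a header row; an ``fd`` column carries framewise
  displacement
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .components import ComponentLoadings
from .connectome import ConfoundSet, ConnectivityMatrix, ParcelTimeSeries
from .graph import FEATURE_ORDER_VERSION, CommunityAssignment


# -- connectomes ------------------------------------------------------------

def write_connectome_tsv(m: ConnectivityMatrix, path) -> None:
    np.savetxt(path, m.weights, delimiter="\t", fmt="%.10g")


def read_connectome_tsv(path) -> ConnectivityMatrix:
    w = np.loadtxt(path, delimiter="\t", ndmin=2)
    return ConnectivityMatrix(w)


# -- communities ------------------------------------------------------------

def write_communities(c: CommunityAssignment, path) -> None:
    df = pd.DataFrame(
        {"node_index": range(c.n_nodes), "network_label": list(c.node_to_network)}
    )
    df.to_csv(path, sep="\t", index=False)


def read_communities(path) -> CommunityAssignment:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("node_index")
    if not np.array_equal(df["node_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("community table must cover node indices 0..n-1")
    return CommunityAssignment(tuple(df["network_label"].astype(str)))


# -- phenotypes -------------------------------------------------------------

def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- feature matrices -------------------------------------------------------

def write_feature_matrix(X: np.ndarray, labels, ids, path) -> None:
    path = Path(path)
    df = pd.DataFrame(np.asarray(X), columns=list(labels))
    df.insert(0, "id", list(ids))
    with open(path, "w") as fh:
        fh.write(f"# feature_order={FEATURE_ORDER_VERSION} units=edge-weight-sums\n")
        df.to_csv(fh, index=False)


def read_feature_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, comment="#")
    ids = df["id"].astype(str).tolist()
    labels = [c for c in df.columns if c != "id"]
    return df[labels].to_numpy(dtype=float), labels, ids


# -- component loadings -----------------------------------------------------

def write_loadings(comp: ComponentLoadings, path) -> None:
    df = pd.DataFrame(
        {
            "feature_label": list(comp.feature_labels),
            "coefficient": comp.coefficients,
            "mean": comp.means,
            "sd": comp.sds,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# component={comp.label} feature_order={FEATURE_ORDER_VERSION}\n"
        )
        df.to_csv(fh, index=False)


def read_loadings(path) -> ComponentLoadings:
    label = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "component=" in first:
            label = int(first.split("component=")[1].split()[0])
    df = pd.read_csv(path, comment="#")
    return ComponentLoadings(
        coefficients=df["coefficient"].to_numpy(dtype=float),
        means=df["mean"].to_numpy(dtype=float),
        sds=df["sd"].to_numpy(dtype=float),
        feature_labels=tuple(df["feature_label"].astype(str)),
        label=label,
    )


# -- time series and confounds ---------------------------------------------

def read_timeseries_tsv(path, tr_seconds: float) -> ParcelTimeSeries:
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return ParcelTimeSeries(values, tr_seconds)


def read_confounds_tsv(path) -> tuple[ConfoundSet, np.ndarray | None]:
    """Confound table with header; returns the confound set (without the
    FD column) and the FD series if an ``fd`` column is present."""
    df = pd.read_csv(path, sep="\t")
    fd = df.pop("fd").to_numpy(dtype=float) if "fd" in df.columns else None
    cs = ConfoundSet(df.to_numpy(dtype=float), list(df.columns))
    return cs, fd
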