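"""Kinetic time-course analysis of annotated metabolites.

Rows are metabolites, columns are (subject, timepoint) pairs.  Missing
values are imputed to half the row minimum, rows are auto-scaled to zero
mean and unit variance, and rows are clustered hierarchically (Ward
linkage on Euclidean distances).  A co-clustering report then checks the
qualitative expectation that phase-II conjugates share the kinetic cluster
of their source metabolite, while microbiome hydrolysis products — which
appear hours later — do not.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import FeatureTable, SampleDesign
from .network import ConjugationNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "build_kinetics_matrix",
    "impute_half_min",
    "autoscale",
    "ward_cluster",
    "coclustering_report",
    "plot_heatmap",
]


def build_kinetics_matrix(table: FeatureTable, design: SampleDesign,
                          network: ConjugationNetwork | None = None,
                          concentrations: pd.DataFrame | None = None,
                          include_pre: bool = True) -> pd.DataFrame:
    """Assemble the metabolite x (subject, timepoint) intensity matrix.

    With a network, rows are nodes (representative-peak intensities);
    otherwise rows are peaks.  ``concentrations`` optionally overrides
    rows with externally quantified values (same column layout); they are
    scaled identically downstream.  Pre-dose samples enter as timepoint 0.
    """
    frame = design.frame
    cols: list[tuple[str, float]] = []
    col_samples: list[str] = []
    classes = ("pre", "post") if include_pre else ("post",)
    human = frame[frame["class"].isin(classes)]
    for _, row in human.iterrows():
        tp = 0.0 if row["class"] == "pre" else float(row["timepoint"])
        cols.append((str(row["subject"]), tp))
        col_samples.append(row["sample_id"])
    order = sorted(range(len(cols)), key=lambda i: cols[i])
    columns = pd.MultiIndex.from_tuples([cols[i] for i in order],
                                        names=["subject", "timepoint"])
    samples = [col_samples[i] for i in order]

    if network is not None:
        rows = []
        index = []
        for node in network.nodes.values():
            rep = node.member_peaks[0]
            if rep not in table.intensity.index:
                logger.warning("node %s representative %s absent from table",
                               node.node_id, rep)
                continue
            rows.append(table.intensity.loc[rep, samples].to_numpy(dtype=float))
            index.append(node.node_id)
        matrix = pd.DataFrame(rows, index=index, columns=columns)
    else:
        matrix = pd.DataFrame(
            table.intensity[samples].to_numpy(dtype=float),
            index=table.intensity.index, columns=columns)

    if concentrations is not None:
        for row_id in concentrations.index:
            if row_id in matrix.index:
                matrix.loc[row_id] = concentrations.loc[row_id].to_numpy(dtype=float)
    return matrix


def impute_half_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by half the row's minimum observed value."""
    out = matrix.copy()
    for row_id, row in out.iterrows():
        if row.isna().all():
            raise ValueError(f"row {row_id!r} has no non-missing values")
        out.loc[row_id] = row.fillna(row.min() / 2.0)
    return out


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (sample standard deviation, n-1 denominator)."""
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("autoscale requires an imputed (complete) matrix")
    sd = values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(str(matrix.index[i]) for i in zero[:5])
        raise ValueError(f"zero-variance row(s): {names}")
    scaled = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterResult:
    """Ward linkage tree with flat labels and the dendrogram leaf order."""

    linkage: np.ndarray                 # scipy linkage matrix, rows-1 merges
    labels: dict[str, int]              # row id -> flat cluster label
    leaf_order: list[str]               # cophenetic (dendrogram) row order

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def ward_cluster(matrix: pd.DataFrame, k: int | None = None,
                 height: float | None = None) -> ClusterResult:
    """Hierarchical clustering of rows: Ward linkage, Euclidean distance.

    Flat labels come from a cluster count ``k`` or a cut ``height``
    (``k`` wins if both are given; default is a single cluster).  Merge
    heights are checked to be non-decreasing on every run.
    """
    if len(matrix) < 2:
        raise ValueError("clustering requires at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    linkage = hierarchy.linkage(values, method="ward", metric="euclidean")
    heights = linkage[:, 2]
    if not np.all(np.diff(heights) >= -1e-9):
        raise AssertionError("Ward merge heights are not non-decreasing")
    if k is not None:
        flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(linkage, t=height, criterion="distance")
    else:
        flat = np.ones(len(matrix), dtype=int)
    order = hierarchy.leaves_list(linkage)
    index = list(matrix.index)
    return ClusterResult(
        linkage=linkage,
        labels={index[i]: int(flat[i]) for i in range(len(index))},
        leaf_order=[index[i] for i in order])


def coclustering_report(result: ClusterResult, network: ConjugationNetwork,
                        ) -> pd.DataFrame:
    """Per-edge table of whether source and conjugate share a cluster.

    Only within-window edges are reported; edges whose endpoints are
    missing from the clustered matrix are skipped with a log entry.  The
    returned frame carries a ``same_cluster`` boolean per edge; summarize
    per reaction with ``df.groupby("reaction")["same_cluster"].mean()``.
    """
    rows = []
    for edge in network.edges:
        if not edge.within_window:
            continue
        if edge.source not in result.labels or edge.target not in result.labels:
            logger.warning("edge %s->%s skipped: endpoint not in matrix",
                           edge.source, edge.target)
            continue
        rows.append({
            "source": edge.source,
            "target": edge.target,
            "reaction": edge.reaction,
            "source_cluster": result.labels[edge.source],
            "target_cluster": result.labels[edge.target],
            "same_cluster": result.labels[edge.source] == result.labels[edge.target],
        })
    return pd.DataFrame(rows, columns=["source", "target", "reaction",
                                       "source_cluster", "target_cluster",
                                       "same_cluster"])


def plot_heatmap(matrix: pd.DataFrame, result: ClusterResult, path) -> None:
    """Render a simple clustered heatmap (rows in dendrogram order)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.loc[result.leaf_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0])))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels(ordered.index, fontsize=6)
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels([f"{s}:{t:g}h" for s, t in ordered.columns],
                       rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="auto-scaled intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
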