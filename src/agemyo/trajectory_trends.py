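"""Pseudotime bin/trend analysis for myonucleus degeneration trajectories.

Cells are rank-ordered along a supplied pseudotime and aggregated into
equal-count bins (default 100).  Downstream summaries: per-bin age-group
occupancy, per-bin marker-panel module scores, bin-level variable-gene
selection and k-means clustering of z-scored gene trends.  Trajectory
*inference* is out of scope: pseudotime is an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .fibre_typing import MarkerPanel, module_score
from .io_qc import NormMatrix

__all__ = [
    "TrendClusters",
    "bin_pseudotime",
    "aggregate_bins",
    "select_variable_genes",
    "cluster_gene_trends",
    "group_proportion_per_bin",
    "panel_score_along_trajectory",
]


def bin_pseudotime(pseudotime, n_bins: int = 100, cell_ids=None) -> np.ndarray:
    """Equal-count bin index (1..n_bins) per cell, monotone in pseudotime.

    Cells are ranked by pseudotime (ties broken by cell id when given, else by
    input position) and split into bins whose sizes differ by at most one;
    the remainder goes to the earliest bins.
    """
    t = np.asarray(pseudotime, dtype=float)
    if np.isnan(t).any():
        raise ValueError("NaN pseudotime")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite pseudotime")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(t) < n_bins:
        raise ValueError(f"{len(t)} cells cannot fill {n_bins} bins")
    if cell_ids is not None:
        order = np.lexsort((np.asarray(cell_ids).astype(str), t))
    else:
        order = np.argsort(t, kind="stable")
    bins = np.empty(len(t), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        bins[chunk] = b
    return bins


def aggregate_bins(nm: NormMatrix, bins: np.ndarray) -> pd.DataFrame:
    """Bin x gene matrix of mean normalized expression."""
    bins = np.asarray(bins)
    if len(bins) != len(nm.cells):
        raise ValueError("bins must cover all cells")
    labels = np.unique(bins)
    X = nm.X.tocsc()
    out = np.empty((len(labels), len(nm.genes)))
    for i, b in enumerate(labels):
        cols = np.where(bins == b)[0]
        if len(cols) == 0:
            raise ValueError(f"empty bin {b}")
        out[i] = np.asarray(X[:, cols].mean(axis=1)).ravel()
    return pd.DataFrame(out, index=labels, columns=nm.genes)


def select_variable_genes(bin_matrix: pd.DataFrame, n_top: int = 4000) -> np.ndarray:
    """Top n_top genes by variance of the binned trend (ties by gene id)."""
    if n_top > bin_matrix.shape[1]:
        raise ValueError("n_top exceeds the number of genes")
    var = bin_matrix.var(axis=0, ddof=0)
    order = np.lexsort((bin_matrix.columns.astype(str), -var.to_numpy()))
    return bin_matrix.columns.to_numpy(dtype=object)[order[:n_top]]


@dataclass
class TrendClusters:
    genes: np.ndarray            # the clustered (selected) genes
    labels: np.ndarray           # cluster id 1..k per gene
    centroids: np.ndarray        # k x n_bins, z-scored trend space
    inertia: float

    def cluster_members(self, k: int) -> np.ndarray:
        return self.genes[self.labels == k]


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def cluster_gene_trends(
    bin_matrix: pd.DataFrame,
    genes,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> TrendClusters:
    """k-means over per-gene z-scored bin trends.

    k-means++ initialisation with *n_init* restarts, best inertia kept;
    clusters are renumbered by the bin index of their centroid's peak (early
    peaks first), making labels deterministic and trajectory-ordered.
    """
    genes = np.asarray(genes, dtype=object)
    if k > len(genes):
        raise ValueError("k exceeds the number of genes")
    M = bin_matrix[genes].to_numpy().T  # genes x bins
    Z = _zscore_rows(M)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(Z)
    peaks = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((np.arange(k), peaks))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return TrendClusters(
        genes=genes,
        labels=remap[raw_labels],
        centroids=km.cluster_centers_[order],
        inertia=float(km.inertia_),
    )


def group_proportion_per_bin(bins: np.ndarray, groups) -> pd.DataFrame:
    """Fraction of adult / old cells per bin (rows sum to 1)."""
    df = pd.DataFrame({"bin": np.asarray(bins), "group": np.asarray(groups)})
    tab = pd.crosstab(df["bin"], df["group"])
    for g in ("adult", "old"):
        if g not in tab.columns:
            tab[g] = 0
    tab = tab[["adult", "old"]]
    props = tab.div(tab.sum(axis=1), axis=0)
    props.columns = ["prop_adult", "prop_old"]
    return props


def panel_score_along_trajectory(
    nm: NormMatrix,
    bins: np.ndarray,
    panel: MarkerPanel,
    n_bins_ctrl: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score averaged within each pseudotime bin."""
    scores = module_score(nm, panel, n_bins=n_bins_ctrl, n_ctrl=n_ctrl, seed=seed)
    s = pd.Series(scores).groupby(np.asarray(bins)).mean()
    s.index.name = "bin"
    s.name = panel.name
    return s
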