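"""Matched-downsampling heterogeneity ("transcriptional noise") statistics.

Per-cell noise is the Euclidean distance of each cell, over expression-
invariant genes, to the centroid of its own (cell type x age group) — after
the two groups have been matched in cell number and per-cell sequencing
depth by random downsampling.  The epigenetic arm applies the identical
pipeline to a rounded gene-activity-score matrix.  The module also houses
the exact/approximate two-tailed Mann-Whitney U-test used package-wide.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import ndtr

from .io_qc import (
    CountMatrix,
    NormMatrix,
    downsample_cells,
    downsample_counts,
    normalize_log1p,
)

__all__ = [
    "InvariantGeneSet",
    "NoiseResult",
    "mann_whitney_u",
    "select_invariant_genes",
    "noise_per_cell",
    "epigenetic_noise_per_cell",
    "round_half_away_from_zero",
]


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + 0.5 * #{x_i == y_j} over all pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-tailed Mann-Whitney U-test.

    Parameters
    ----------
    x, y
        The two samples (nonempty).
    mode
        ``"exact"`` enumerates all C(n+m, n) group assignments of the pooled
        values (ties handled by enumeration); ``"normal_tie_corrected"`` uses
        the normal approximation with tie-corrected variance and a 0.5
        continuity correction; ``"auto"`` picks exact when n + m <= 12.

    Returns
    -------
    (U, p)
        U for the *x* sample and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: both samples must be nonempty")
    n, m = x.size, y.size
    U = _u_statistic(x, y)

    if mode == "auto":
        mode = "exact" if n + m <= 12 else "normal_tie_corrected"
    if mode == "exact":
        pooled = np.concatenate([x, y])
        N = n + m
        mid = n * m / 2.0
        dev = abs(U - mid)
        # pairwise win matrix of the pooled values; U of an assignment is the
        # sum of W over (in-group, out-group) pairs
        W = (pooled[:, None] > pooled[None, :]) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        np.fill_diagonal(W, 0.0)
        combs = np.array(list(itertools.combinations(range(N), n)))
        M = np.zeros((len(combs), N))
        M[np.arange(len(combs))[:, None], combs] = 1.0
        u_all = ((M @ W) * (1.0 - M)).sum(axis=1)
        hits = int((np.abs(u_all - mid) >= dev - 1e-12).sum())
        return U, hits / len(combs)
    if mode == "normal_tie_corrected":
        N = n + m
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            return U, 1.0
        z = (abs(U - n * m / 2.0) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = 2.0 * (1.0 - ndtr(z))
        return U, min(1.0, p)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Invariant-gene selection


@dataclass
class InvariantGeneSet:
    """Lowest-CV genes per average-expression block.

    ``table`` holds every expressed gene with its mean, CV (sd/mean, sample
    sd), block index (1..n_blocks, ranked by increasing mean) and a
    ``selected`` flag; ``genes`` is the selected union in table order.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> np.ndarray:
        return self.table.loc[self.table["selected"], "gene"].to_numpy(dtype=object)


def select_invariant_genes(
    nm: NormMatrix, n_blocks: int = 10, lowest_frac: float = 0.1
) -> InvariantGeneSet:
    """Rank expressed genes by mean into blocks; keep the lowest-CV fraction per block.

    Genes with zero mean are excluded first.  Blocks are near-equal: size
    floor(G/n_blocks), with the remainder going to the highest-expression
    blocks.  Within each block the ceil(lowest_frac * block_size) genes with
    smallest CV are selected; ties (in mean or CV) break by gene id.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not 0 < lowest_frac <= 1:
        raise ValueError("lowest_frac must lie in (0, 1]")
    X = nm.X
    n_cells = X.shape[1]
    means = np.asarray(X.mean(axis=1)).ravel()
    sumsq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    if n_cells > 1:
        var = (sumsq - n_cells * means**2) / (n_cells - 1)
        var = np.maximum(var, 0.0)
    else:
        var = np.zeros_like(means)
    expressed = means > 0
    G = int(expressed.sum())
    if G < n_blocks:
        raise ValueError(f"only {G} expressed genes for {n_blocks} blocks")

    genes = nm.genes[expressed]
    mu = means[expressed]
    cv = np.sqrt(var[expressed]) / mu

    order = np.lexsort((genes.astype(str), mu))  # ascending mean, id tiebreak
    base, rem = divmod(G, n_blocks)
    sizes = [base] * (n_blocks - rem) + [base + 1] * rem  # remainder to high-expression
    block = np.empty(G, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        block[order[start : start + size]] = b
        start += size

    selected = np.zeros(G, dtype=bool)
    for b in range(1, n_blocks + 1):
        members = np.where(block == b)[0]
        k = math.ceil(lowest_frac * len(members))
        sub = members[np.lexsort((genes[members].astype(str), cv[members]))]
        selected[sub[:k]] = True

    table = pd.DataFrame(
        {"gene": genes, "mean": mu, "cv": cv, "block": block, "selected": selected}
    )
    return InvariantGeneSet(table=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Noise pipeline


@dataclass
class NoiseResult:
    """Per-cell heterogeneity distances plus a per-cell-type group comparison."""

    cell_type: str
    per_cell: pd.DataFrame  # cell_id, group, distance
    median_adult: float
    median_old: float
    U: float
    p: float
    target_total: int
    n_per_group: int
    invariant_genes: np.ndarray


def _group_distances(
    values: np.ndarray, groups: np.ndarray, mode: str
) -> np.ndarray:
    """Distance of each cell (columns of *values*) within its own group."""
    dist = np.empty(values.shape[1])
    for g in np.unique(groups):
        cols = np.where(groups == g)[0]
        V = values[:, cols]
        if mode == "centroid":
            centroid = V.mean(axis=1, keepdims=True)
            dist[cols] = np.sqrt(((V - centroid) ** 2).sum(axis=0))
        elif mode == "pairwise":
            # mean Euclidean distance to the other cells of the group
            sq = (V**2).sum(axis=0)
            d2 = sq[:, None] + sq[None, :] - 2.0 * (V.T @ V)
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(np.maximum(d2, 0.0))
            k = max(V.shape[1] - 1, 1)
            dist[cols] = d.sum(axis=1) / k
        else:
            raise ValueError(f"unknown distance mode {mode!r}")
    return dist


def noise_per_cell(
    m: CountMatrix,
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    cell_type: str,
    n_max: int = 300,
    seed=0,
    mode: str = "centroid",
    target_sum: float = 1e4,
    n_blocks: int = 10,
    lowest_frac: float = 0.1,
) -> NoiseResult:
    """Matched-downsampling heterogeneity for one cell type.

    Pipeline: (i) downsample each age group to min(n_max, group size) cells;
    (ii) equalize cell numbers across groups; (iii) downsample every retained
    cell to the common minimum total count; (iv) log-normalize; (v) select
    invariant genes (10 blocks, lowest 10% CV) on the pooled matched matrix;
    (vi) per-cell Euclidean distance to its own group centroid over those
    genes.  Groups are then compared with a two-tailed Mann-Whitney U-test.
    """
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    meta = cell_meta.merge(
        sample_meta[["sample_id", "age_group"]], on="sample_id", how="left"
    )
    if meta["age_group"].isna().any():
        raise ValueError("cells reference samples missing from sample_meta")
    sub = meta[meta["cell_type"] == cell_type]

    # downsampling randomness is keyed on each group's cell ids, not its
    # label, so that swapping the group labels leaves the retained cells (and
    # hence every distance) unchanged
    def _ids_rng(ids, salt):
        key = zlib.crc32("\x00".join(sorted(map(str, ids))).encode())
        return np.random.default_rng(np.random.SeedSequence([seed, salt, key]))

    ids_by_group = {}
    for g in ("adult", "old"):
        ids = sub.loc[sub["age_group"] == g, "cell_id"].to_numpy(dtype=object)
        if len(ids) == 0:
            raise ValueError(f"age group {g!r} absent for cell type {cell_type!r}")
        ids_by_group[g] = downsample_cells(ids, n_max, _ids_rng(ids, 0))
    n_common = min(len(v) for v in ids_by_group.values())
    for g in ids_by_group:
        ids = ids_by_group[g]
        ids_by_group[g] = downsample_cells(ids, n_common, _ids_rng(ids, 1))

    cell_ids = np.concatenate([ids_by_group["adult"], ids_by_group["old"]])
    groups = np.array(["adult"] * n_common + ["old"] * n_common, dtype=object)
    order = np.argsort(cell_ids.astype(str))  # canonical, label-independent order
    cell_ids, groups = cell_ids[order], groups[order]
    sub_m = m.subset_cells(cell_ids)
    target = int(sub_m.cell_totals().min())
    if target == 0:
        raise ValueError("common target total is 0; filter empty cells first")
    matched = downsample_counts(sub_m, target, _ids_rng(cell_ids, 2))
    nm = normalize_log1p(matched, target_sum=target_sum)
    inv = select_invariant_genes(nm, n_blocks=n_blocks, lowest_frac=lowest_frac)
    values = np.asarray(nm.subset_genes(inv.genes).X.todense())
    dist = _group_distances(values, groups, mode)

    adult_d = dist[groups == "adult"]
    old_d = dist[groups == "old"]
    U, p = mann_whitney_u(adult_d, old_d, mode="auto")
    per_cell = pd.DataFrame(
        {"cell_id": cell_ids, "cell_type": cell_type, "group": groups, "distance": dist}
    )
    return NoiseResult(
        cell_type=cell_type,
        per_cell=per_cell,
        median_adult=float(np.median(adult_d)),
        median_old=float(np.median(old_d)),
        U=U,
        p=p,
        target_total=target,
        n_per_group=n_common,
        invariant_genes=inv.genes,
    )


def round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    """Round to integer with halves going away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def epigenetic_noise_per_cell(
    gene_scores,
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    cell_type: str,
    n_max: int = 300,
    seed=0,
    **kwargs,
) -> NoiseResult:
    """Heterogeneity on a gene-activity-score matrix.

    Scores are rounded half-away-from-zero to integers and then fed through
    the :func:`noise_per_cell` pipeline verbatim.
    """
    X = gene_scores.X
    if sp.issparse(X):
        X = X.copy()
        X.data = round_half_away_from_zero(X.data)
        X = X.astype(np.int64)
    else:
        X = sp.csr_matrix(round_half_away_from_zero(np.asarray(X)))
    if X.nnz and X.data.min() < 0:
        raise ValueError("gene activity scores must be nonnegative")
    counts = CountMatrix(np.asarray(gene_scores.genes, dtype=object),
                         np.asarray(gene_scores.cells, dtype=object), X)
    return noise_per_cell(
        counts, cell_meta, sample_meta, cell_type, n_max=n_max, seed=seed, **kwargs
    )
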