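"""Marker-panel module scoring and the two-tier myonucleus fibre-type classifier.

Module scores follow the bin-matched control-gene scheme: the score of a cell
is the mean normalized expression of the panel genes minus the mean of control
genes drawn from the same average-expression bins.  Classification is
hierarchical: tier 1 separates type I / type II / hybrid I/IIA (slow myosin
MYH7 vs fast MYH1/MYH2 programs); tier 2 splits type II nuclei into IIA / IIX
/ hybrid IIA/IIX.  Nuclei with uniformly weak scores stay unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .heterogeneity import mann_whitney_u
from .io_qc import NormMatrix

__all__ = [
    "MarkerPanel",
    "ModuleScores",
    "builtin_panels",
    "load_panels",
    "module_score",
    "compute_module_scores",
    "classify_fibre_types",
    "fibre_proportions",
    "compare_proportions",
    "FIBRE_CLASSES",
]

FIBRE_CLASSES = ["I", "IIA", "IIX", "hybrid I/IIA", "hybrid IIA/IIX", "unclassified"]


@dataclass
class MarkerPanel:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker panel {self.name!r} is empty")


def load_panels(path) -> dict[str, MarkerPanel]:
    """Read panels from a YAML/JSON mapping {panel_name: [gene, ...]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: MarkerPanel(name, list(genes)) for name, genes in raw.items()}


def builtin_panels() -> dict[str, MarkerPanel]:
    """The four shipped myofibre panels (type_I, type_II, type_IIA, type_IIX)."""
    ref = resources.files("agemyo").joinpath("data/markers.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {name: MarkerPanel(name, list(genes)) for name, genes in raw.items()}


@dataclass
class ModuleScores:
    cells: np.ndarray
    panel_names: list[str]
    scores: np.ndarray  # cells x panels

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.cells), len(self.panel_names)):
            raise ValueError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite module scores")


def _expression_bins(means: np.ndarray, gene_ids: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign every gene to one of n_bins near-equal rank bins by mean expression."""
    order = np.lexsort((gene_ids.astype(str), means))
    bins = np.empty(len(means), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    nm: NormMatrix,
    panel: MarkerPanel,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed=0,
) -> np.ndarray:
    """Per-cell module score for one panel.

    For each panel gene, ``n_ctrl`` control genes are sampled from the
    gene's average-expression bin (without replacement when the bin is large
    enough, with replacement otherwise).  score = mean(panel) - mean(controls).
    Missing panel genes are dropped with a warning; a fully absent panel is an
    error.  Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(nm.genes)}
    present = [g for g in panel.genes if g in gene_index]
    missing = [g for g in panel.genes if g not in gene_index]
    if missing:
        warnings.warn(
            f"panel {panel.name!r}: dropping {len(missing)} absent genes {missing}",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"panel {panel.name!r} entirely absent from matrix")

    X = nm.X
    means = np.asarray(X.mean(axis=1)).ravel()
    bins = _expression_bins(means, nm.genes, n_bins)

    panel_idx = np.array([gene_index[g] for g in present])
    ctrl_idx: list[np.ndarray] = []
    for gi in panel_idx:
        members = np.where(bins == bins[gi])[0]
        replace = len(members) < n_ctrl
        ctrl_idx.append(rng.choice(members, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)

    panel_mean = np.asarray(X[panel_idx, :].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[ctrl, :].mean(axis=0)).ravel()
    return panel_mean - ctrl_mean


def compute_module_scores(
    nm: NormMatrix,
    panels: dict[str, MarkerPanel] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed=0,
) -> ModuleScores:
    """Module scores for several panels (defaults to the builtin fibre panels).

    Each panel gets an independent control draw from a seed spawned off
    *seed*, so adding a panel never perturbs the others' scores.
    """
    panels = panels or builtin_panels()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(panels))
    cols = []
    names = []
    for child, (name, panel) in zip(children, panels.items()):
        cols.append(module_score(nm, panel, n_bins=n_bins, n_ctrl=n_ctrl,
                                 seed=np.random.default_rng(child)))
        names.append(name)
    return ModuleScores(
        cells=np.asarray(nm.cells, dtype=object),
        panel_names=names,
        scores=np.column_stack(cols),
    )


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def classify_fibre_types(
    ms: ModuleScores,
    tau_unclassified: float = 0.0,
    delta_hybrid: float = 0.5,
) -> pd.DataFrame:
    """Hierarchical fibre-type calls from z-standardized module scores.

    Tier 1: unclassified if max(z_I, z_II) < tau; hybrid I/IIA if
    min(z_I, z_IIA) >= tau and |z_I - z_IIA| < delta; else argmax(z_I, z_II)
    (ties to type I).  Tier 2 (type II only): unclassified if
    max(z_IIA, z_IIX) < tau; hybrid IIA/IIX if both >= tau and
    |z_IIA - z_IIX| < delta; else argmax (ties to IIA).

    Returns a DataFrame with columns cell_id, tier1, tier2, final_class.
    """
    required = ["type_I", "type_II", "type_IIA", "type_IIX"]
    for name in required:
        if name not in ms.panel_names:
            raise ValueError(f"missing panel {name!r} in module scores")
    z = {name: _zscore(ms.scores[:, ms.panel_names.index(name)]) for name in required}
    zI, zII, zIIA, zIIX = (z[n] for n in required)

    n = len(ms.cells)
    tier1 = np.empty(n, dtype=object)
    tier2 = np.full(n, "n/a", dtype=object)

    tau, delta = tau_unclassified, delta_hybrid
    uncls1 = np.maximum(zI, zII) < tau
    hyb1 = (~uncls1) & (np.minimum(zI, zIIA) >= tau) & (np.abs(zI - zIIA) < delta)
    is_I = (~uncls1) & (~hyb1) & (zI >= zII)  # tie to the oxidative class
    is_II = (~uncls1) & (~hyb1) & (zI < zII)
    tier1[uncls1] = "unclassified"
    tier1[hyb1] = "hybrid I/IIA"
    tier1[is_I] = "type I"
    tier1[is_II] = "type II"

    uncls2 = is_II & (np.maximum(zIIA, zIIX) < tau)
    hyb2 = (
        is_II
        & (~uncls2)
        & (np.minimum(zIIA, zIIX) >= tau)
        & (np.abs(zIIA - zIIX) < delta)
    )
    iia = is_II & (~uncls2) & (~hyb2) & (zIIA >= zIIX)
    iix = is_II & (~uncls2) & (~hyb2) & (zIIA < zIIX)
    tier2[uncls2] = "unclassified"
    tier2[hyb2] = "hybrid IIA/IIX"
    tier2[iia] = "IIA"
    tier2[iix] = "IIX"

    final = np.empty(n, dtype=object)
    final[uncls1] = "unclassified"
    final[hyb1] = "hybrid I/IIA"
    final[is_I] = "I"
    final[uncls2] = "unclassified"
    final[hyb2] = "hybrid IIA/IIX"
    final[iia] = "IIA"
    final[iix] = "IIX"

    return pd.DataFrame(
        {"cell_id": ms.cells, "tier1": tier1, "tier2": tier2, "final_class": final}
    )


def fibre_proportions(
    calls: pd.DataFrame,
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample proportions of the six final fibre classes.

    Returns a long table (sample_id, age_group, final_class, proportion);
    proportions sum to 1 within each sample.  Samples contributing zero
    classified nuclei are excluded with a warning.
    """
    meta = calls.merge(cell_meta[["cell_id", "sample_id"]], on="cell_id", how="left")
    if meta["sample_id"].isna().any():
        orphans = meta.loc[meta["sample_id"].isna(), "cell_id"].head(3).tolist()
        raise ValueError(f"calls contain cells absent from cell_meta: {orphans}")

    groups = sample_meta.set_index("sample_id")["age_group"]
    rows = []
    for sample_id, sub in meta.groupby("sample_id"):
        total = len(sub)
        if total == 0:
            warnings.warn(f"sample {sample_id!r} has no myonuclei; excluded",
                          stacklevel=2)
            continue
        counts = sub["final_class"].value_counts()
        for cls in FIBRE_CLASSES:
            rows.append(
                {
                    "sample_id": sample_id,
                    "age_group": groups.get(sample_id),
                    "final_class": cls,
                    "proportion": counts.get(cls, 0) / total,
                }
            )
    return pd.DataFrame(rows)


def compare_proportions(
    prop_table: pd.DataFrame, sample_meta: pd.DataFrame, class_name: str
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U on adult vs old per-sample proportions of one class."""
    sub = prop_table[prop_table["final_class"] == class_name]
    merged = sub.merge(sample_meta[["sample_id", "age_group"]], on="sample_id",
                       how="left", suffixes=("", "_sm"))
    grp = merged["age_group_sm"] if "age_group_sm" in merged else merged["age_group"]
    adult = merged.loc[grp == "adult", "proportion"].to_numpy()
    old = merged.loc[grp == "old", "proportion"].to_numpy()
    if adult.size == 0 or old.size == 0:
        raise ValueError("both age groups need at least one sample")
    return mann_whitney_u(adult, old, mode="auto")
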