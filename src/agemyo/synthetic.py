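"""Synthetic ageing-muscle atlas generator with known ground truth.

Emulates the statistical structure every downstream stage assumes: ~15 cell
types with marker programs; myonuclei carrying the shipped fibre-type marker
panels (type I / IIA / IIX plus 50/50 hybrids); two age groups with
cell-type-specific abundance tilts, cell-type-specific negative-binomial
overdispersion, and a latent degeneration pseudotime with age-ordered
occupancy and monotone / abrupt gene trends; multiple samples carrying
sex / ethnicity / batch / modality covariates.

Counts are negative-binomial with mean mu and dispersion phi
(Var = mu + phi * mu^2, gamma-Poisson mixture; phi = 0 degenerates to
Poisson), with per-cell totals set by a lognormal library size and a
Beta-distributed mitochondrial fraction routed to the MT- genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fibre_typing import builtin_panels
from .io_qc import CountMatrix, read_matrix, write_matrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "GeneScoreMatrix",
    "MYONUCLEUS_TYPES",
    "generate_atlas",
    "generate_gene_scores",
    "write_fixture",
    "read_fixture",
]

MYONUCLEUS_TYPES = ("type_I_myonuclei", "type_II_myonuclei")

TREND_ARCHETYPES = ("monotone_up", "monotone_down", "late_abrupt_up", "flat")
_ARCH_PREFIX = {
    "monotone_up": "TRUP",
    "monotone_down": "TRDN",
    "late_abrupt_up": "TRAB",
    "flat": "TRFL",
}


def _default_props() -> dict[str, float]:
    return {
        "type_I_myonuclei": 0.20,
        "type_II_myonuclei": 0.25,
        "NMJ_myonuclei": 0.015,
        "MTJ_myonuclei": 0.015,
        "MuSC": 0.05,
        "FAP": 0.12,
        "fibroblast": 0.04,
        "adipocyte": 0.02,
        "EC": 0.10,
        "SMC": 0.03,
        "pericyte": 0.05,
        "myeloid": 0.05,
        "lymphoid": 0.03,
        "mast": 0.01,
        "Schwann": 0.02,
    }


def _default_age_effects() -> dict[str, float]:
    # old-vs-adult abundance log fold changes: myonuclear loss dominated by
    # type II, MuSC/pericyte decline, stromal/immune expansion
    return {
        "type_I_myonuclei": 0.15,
        "type_II_myonuclei": -0.5,
        "MuSC": -0.4,
        "pericyte": -0.3,
        "adipocyte": 0.6,
        "fibroblast": 0.5,
        "myeloid": 0.4,
        "lymphoid": 0.3,
        "mast": 0.3,
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_samples_per_group: int = 8
    n_cells_per_sample: int = 1000
    n_genes: int = 2000
    cell_type_props: dict[str, float] = field(default_factory=_default_props)
    age_effects: dict[str, float] = field(default_factory=_default_age_effects)
    dispersion: dict = field(default_factory=dict)  # (cell_type, group) -> phi
    default_dispersion: float = 0.3
    marker_effect: float = 4.0
    hybrid_frac: float = 0.1
    iix_frac_within_type_II: float = 0.45
    libsize_lognormal: tuple[float, float] = (8.0, 0.4)
    mito_frac_beta: tuple[float, float] = (2.0, 98.0)
    pseudotime_trend_genes: dict[str, int] = field(
        default_factory=lambda: {a: 40 for a in TREND_ARCHETYPES}
    )
    pseudotime_beta_adult: tuple[float, float] = (1.5, 3.0)
    pseudotime_beta_old: tuple[float, float] = (3.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group <= 0 or self.n_cells_per_sample <= 0:
            raise ValueError("sample/cell counts must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        total = sum(self.cell_type_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_type_props sum to {total}, not 1")
        if any(p < 0 for p in self.cell_type_props.values()):
            raise ValueError("negative cell-type proportion")
        if self.default_dispersion < 0 or any(v < 0 for v in self.dispersion.values()):
            raise ValueError("dispersion phi must be >= 0")
        if self.marker_effect <= 1:
            raise ValueError("marker_effect must exceed 1")
        if not 0 <= self.hybrid_frac < 1:
            raise ValueError("hybrid_frac must lie in [0, 1)")
        unknown = set(self.age_effects) - set(self.cell_type_props)
        if unknown:
            raise ValueError(f"age_effects for unknown cell types: {sorted(unknown)}")

    def phi(self, cell_type: str, group: str) -> float:
        return float(self.dispersion.get((cell_type, group), self.default_dispersion))


@dataclass
class SimTruth:
    """Latent ground truth emitted alongside a simulated atlas."""

    cell_type: pd.Series            # per cell_id
    fibre_type: pd.Series           # per cell_id; 'n/a' outside myofibre nuclei
    pseudotime: pd.Series           # per cell_id; NaN outside myofibre nuclei
    dispersion: dict                # (cell_type, group) -> phi used
    configured_age_effects: dict
    realized_age_log_fc: dict       # cell_type -> empirical old/adult log ratio
    gene_archetype: dict            # trend gene -> archetype
    marker_genes: dict              # fibre type -> elevated genes


@dataclass
class GeneScoreMatrix:
    """Dense nonnegative gene-activity matrix (genes x cells)."""

    genes: np.ndarray
    cells: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError("shape mismatch")
        if self.X.size and self.X.min() < 0:
            raise ValueError("negative activity")


# ---------------------------------------------------------------------------
# gene universe and mean profiles


def _build_gene_universe(config: SimConfig) -> tuple[np.ndarray, dict, dict]:
    n_mito = math.ceil(0.01 * config.n_genes)
    mito = [f"MT-{i:04d}" for i in range(1, n_mito + 1)]
    panels = builtin_panels()
    marker_union: list[str] = []
    for panel in panels.values():
        for g in panel.genes:
            if g not in marker_union:
                marker_union.append(g)
    trend: list[str] = []
    gene_archetype: dict[str, str] = {}
    for arch in TREND_ARCHETYPES:
        for i in range(1, config.pseudotime_trend_genes.get(arch, 0) + 1):
            name = f"{_ARCH_PREFIX[arch]}-{i:04d}"
            trend.append(name)
            gene_archetype[name] = arch
    n_named = len(mito) + len(marker_union) + len(trend)
    if config.n_genes < n_named + 10:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {n_named} named genes"
        )
    filler = [f"G{i:05d}" for i in range(1, config.n_genes - n_named + 1)]
    genes = np.array(mito + marker_union + trend + filler, dtype=object)
    panel_genes = {name: list(p.genes) for name, p in panels.items()}
    return genes, gene_archetype, panel_genes


def _trend_factor(arch: str, t: np.ndarray) -> np.ndarray:
    if arch == "monotone_up":
        return 0.5 + 2.0 * t
    if arch == "monotone_down":
        return 2.5 - 2.0 * t
    if arch == "late_abrupt_up":
        # transition width ~0.05 in pseudotime, i.e. a few bins of a 100-bin
        # ordering — genuinely abrupt, in contrast to the monotone archetypes
        return 0.5 + 2.0 / (1.0 + np.exp(-(t - 0.8) * 80.0))
    if arch == "flat":
        return np.ones_like(t)
    raise ValueError(f"unknown archetype {arch!r}")


def _base_profiles(config: SimConfig, genes, gene_archetype, panel_genes, rng):
    """Per-identity mean profiles over non-mito genes, normalised to sum 1."""
    G = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    mito_mask = np.array([g.startswith("MT-") for g in genes])
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    baseline[mito_mask] = baseline[mito_mask].mean()  # mito handled via fraction
    # fibre markers are uniformly well-expressed sarcomeric/metabolic genes;
    # a shared baseline keeps the panels comparable before elevation
    marker_union = {g for p in panel_genes.values() for g in p}
    marker_idx = [i for i, g in enumerate(genes) if g in marker_union]
    baseline[marker_idx] = math.exp(0.5)

    # identity programs: each cell type elevates a private block of filler genes
    filler_idx = [i for i, g in enumerate(genes)
                  if g.startswith("G") and not g.startswith("MT-")]
    per_type = 20
    programs: dict[str, np.ndarray] = {}
    pool = rng.permutation(filler_idx)
    for k, ct in enumerate(config.cell_type_props):
        block = pool[k * per_type : (k + 1) * per_type]
        programs[ct] = np.asarray(block, dtype=int)

    fibre_elevated = {
        "I": panel_genes["type_I"],
        "IIA": sorted(set(panel_genes["type_II"]) | set(panel_genes["type_IIA"])),
        "IIX": sorted(set(panel_genes["type_II"]) | set(panel_genes["type_IIX"])),
    }

    profiles: dict[str, np.ndarray] = {}

    def finish(v: np.ndarray) -> np.ndarray:
        v = v.copy()
        v[mito_mask] = 0.0
        return v / v.sum()

    for ct in config.cell_type_props:
        v = baseline.copy()
        if len(programs[ct]):
            v[programs[ct]] *= config.marker_effect
        profiles[f"ct:{ct}"] = finish(v)
    for ft, elev in fibre_elevated.items():
        base_ct = "type_I_myonuclei" if ft == "I" else "type_II_myonuclei"
        v = baseline.copy()
        prog = programs.get(base_ct, np.array([], dtype=int))
        if len(prog):
            v[prog] *= config.marker_effect
        for g in elev:
            v[gidx[g]] *= config.marker_effect
        profiles[f"fibre:{ft}"] = finish(v)
    profiles["fibre:hybrid I/IIA"] = (
        0.5 * profiles["fibre:I"] + 0.5 * profiles["fibre:IIA"]
    )
    profiles["fibre:hybrid IIA/IIX"] = (
        0.5 * profiles["fibre:IIA"] + 0.5 * profiles["fibre:IIX"]
    )
    truth_markers = {ft: list(ev) for ft, ev in fibre_elevated.items()}
    return profiles, mito_mask, gene_archetype, truth_markers


def _sample_covariates(config: SimConfig) -> pd.DataFrame:
    rows = []
    sexes = ["female", "male"]
    ethnicities = ["ES", "CN"]
    batches = ["b1", "b2", "b3", "b4"]
    modalities = ["snRNA", "scRNA"]
    adult_ages = np.linspace(20, 46, config.n_samples_per_group)
    old_ages = np.linspace(74, 95, config.n_samples_per_group)
    for gi, (group, ages) in enumerate([("adult", adult_ages), ("old", old_ages)]):
        for i in range(config.n_samples_per_group):
            rows.append(
                {
                    "sample_id": f"{group}_s{i:02d}",
                    "age_years": round(float(ages[i]), 1),
                    "age_group": group,
                    "sex": sexes[i % 2],
                    "ethnicity": ethnicities[(i // 2) % 2],
                    "batch": batches[i % 4],
                    "modality": modalities[i % 2],
                }
            )
    return pd.DataFrame(rows)


def _assign_cells(config: SimConfig, sample_meta: pd.DataFrame, rng):
    """Per-cell type / fibre type / pseudotime assignment, sample by sample."""
    cell_types = list(config.cell_type_props)
    base = np.array([config.cell_type_props[ct] for ct in cell_types])
    records = []
    for _, srow in sample_meta.iterrows():
        group = srow["age_group"]
        tilt = np.array(
            [
                math.exp(config.age_effects.get(ct, 0.0)) if group == "old" else 1.0
                for ct in cell_types
            ]
        )
        p = base * tilt
        p = p / p.sum()
        counts = rng.multinomial(config.n_cells_per_sample, p)
        a, b = (
            config.pseudotime_beta_adult if group == "adult"
            else config.pseudotime_beta_old
        )
        ci = 0
        for ct, k in zip(cell_types, counts):
            for _ in range(k):
                fibre = "n/a"
                t = np.nan
                if ct in MYONUCLEUS_TYPES:
                    if rng.random() < config.hybrid_frac:
                        fibre = (
                            "hybrid I/IIA"
                            if ct == "type_I_myonuclei" or rng.random() < 0.5
                            else "hybrid IIA/IIX"
                        )
                    elif ct == "type_I_myonuclei":
                        fibre = "I"
                    else:
                        fibre = (
                            "IIX"
                            if rng.random() < config.iix_frac_within_type_II
                            else "IIA"
                        )
                    t = rng.beta(a, b)
                records.append(
                    {
                        "cell_id": f"{srow['sample_id']}_c{ci:05d}",
                        "sample_id": srow["sample_id"],
                        "cell_type": ct,
                        "modality": srow["modality"],
                        "fibre_type": fibre,
                        "pseudotime": t,
                        "age_group": group,
                    }
                )
                ci += 1
    return pd.DataFrame(records)


def _rate_matrix(config, cells, genes, profiles, mito_mask, gene_archetype, rng):
    """Per-cell expected count vectors (cells x genes)."""
    G = len(genes)
    n = len(cells)
    mito_profile = np.zeros(G)
    mito_profile[mito_mask] = 1.0 / max(mito_mask.sum(), 1)
    lib = rng.lognormal(*config.libsize_lognormal, size=n)
    mito_f = rng.beta(*config.mito_frac_beta, size=n)

    arch_cols = {
        arch: np.array([i for i, g in enumerate(genes)
                        if gene_archetype.get(g) == arch], dtype=int)
        for arch in TREND_ARCHETYPES
    }
    R = np.empty((n, G))
    for i, row in enumerate(cells.itertuples(index=False)):
        key = f"fibre:{row.fibre_type}" if row.fibre_type != "n/a" else f"ct:{row.cell_type}"
        prof = profiles[key].copy()
        if row.fibre_type != "n/a" and not np.isnan(row.pseudotime):
            t = np.array([row.pseudotime])
            for arch, cols in arch_cols.items():
                if len(cols):
                    prof[cols] *= _trend_factor(arch, t)[0]
            prof = prof / prof.sum()
        R[i] = ((1.0 - mito_f[i]) * prof + mito_f[i] * mito_profile) * lib[i]
    return R


def _nb_draw(R: np.ndarray, phi: float, rng) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(R)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * R)
    return rng.poisson(lam)


def generate_atlas(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate counts, metadata and latent truth; reproducible from config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, gene_archetype, panel_genes = _build_gene_universe(config)
    profiles, mito_mask, gene_archetype, truth_markers = _base_profiles(
        config, genes, gene_archetype, panel_genes, rng
    )
    sample_meta = _sample_covariates(config)
    cells = _assign_cells(config, sample_meta, rng)

    blocks = []
    for sample_id, sub in cells.groupby("sample_id", sort=False):
        R = _rate_matrix(config, sub, genes, profiles, mito_mask, gene_archetype, rng)
        counts = np.empty_like(R, dtype=np.int64)
        group = sub["age_group"].iloc[0]
        for ct in sub["cell_type"].unique():
            mask = (sub["cell_type"] == ct).to_numpy()
            counts[mask] = _nb_draw(R[mask], config.phi(ct, group), rng)
        blocks.append(sp.csr_matrix(counts))
    X = sp.vstack(blocks).T.tocsr()  # genes x cells

    matrix = CountMatrix(genes, cells["cell_id"].to_numpy(dtype=object), X)
    cell_meta = cells[["cell_id", "sample_id", "cell_type", "modality"]].copy()

    # realized abundance log fold changes (old vs adult mean per-sample proportion)
    realized = {}
    tab = pd.crosstab(cells["sample_id"], cells["cell_type"]).apply(
        lambda r: r / r.sum(), axis=1
    )
    grp = sample_meta.set_index("sample_id")["age_group"]
    for ct in config.cell_type_props:
        if ct not in tab.columns:
            realized[ct] = float("nan")
            continue
        adult_p = tab.loc[grp[tab.index] == "adult", ct].mean()
        old_p = tab.loc[grp[tab.index] == "old", ct].mean()
        realized[ct] = float(np.log(old_p / adult_p)) if adult_p > 0 and old_p > 0 else float("nan")

    truth = SimTruth(
        cell_type=cells.set_index("cell_id")["cell_type"],
        fibre_type=cells.set_index("cell_id")["fibre_type"],
        pseudotime=cells.set_index("cell_id")["pseudotime"],
        dispersion={
            (ct, g): config.phi(ct, g)
            for ct in config.cell_type_props
            for g in ("adult", "old")
        },
        configured_age_effects=dict(config.age_effects),
        realized_age_log_fc=realized,
        gene_archetype=gene_archetype,
        marker_genes=truth_markers,
    )
    return matrix, cell_meta, sample_meta, truth


def generate_gene_scores(
    config: SimConfig,
) -> tuple[GeneScoreMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Gamma-distributed gene-activity matrix with the atlas' group/dispersion structure.

    activity ~ Gamma(shape = 1/phi, scale = phi * mu) per gene (mean mu,
    variance phi * mu^2); phi = 0 yields the deterministic mean.  The result
    is meant to be rounded by the epigenetic-noise pipeline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, gene_archetype, panel_genes = _build_gene_universe(config)
    profiles, mito_mask, gene_archetype, _ = _base_profiles(
        config, genes, gene_archetype, panel_genes, rng
    )
    sample_meta = _sample_covariates(config)
    cells = _assign_cells(config, sample_meta, rng)

    blocks = []
    for sample_id, sub in cells.groupby("sample_id", sort=False):
        R = _rate_matrix(config, sub, genes, profiles, mito_mask, gene_archetype, rng)
        act = np.empty_like(R)
        group = sub["age_group"].iloc[0]
        for ct in sub["cell_type"].unique():
            mask = (sub["cell_type"] == ct).to_numpy()
            phi = config.phi(ct, group)
            if phi <= 0:
                act[mask] = R[mask]
            else:
                act[mask] = rng.gamma(shape=1.0 / phi, scale=phi * R[mask])
        blocks.append(act)
    X = np.vstack(blocks).T  # genes x cells

    gs = GeneScoreMatrix(genes, cells["cell_id"].to_numpy(dtype=object), X)
    cell_meta = cells[["cell_id", "sample_id", "cell_type", "modality"]].copy()
    truth = SimTruth(
        cell_type=cells.set_index("cell_id")["cell_type"],
        fibre_type=cells.set_index("cell_id")["fibre_type"],
        pseudotime=cells.set_index("cell_id")["pseudotime"],
        dispersion={
            (ct, g): config.phi(ct, g)
            for ct in config.cell_type_props
            for g in ("adult", "old")
        },
        configured_age_effects=dict(config.age_effects),
        realized_age_log_fc={},
        gene_archetype=gene_archetype,
        marker_genes={},
    )
    return gs, cell_meta, sample_meta, truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    matrix: CountMatrix,
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    truth: SimTruth | None,
    dir_path,
    config: SimConfig | None = None,
) -> dict:
    """Write matrix.mtx + TSV sidecars + manifest.json; returns the manifest."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    if set(cell_meta["cell_id"]) != set(matrix.cells):
        raise ValueError("cell_meta ids do not match matrix cells")
    if not set(cell_meta["sample_id"]).issubset(set(sample_meta["sample_id"])):
        raise ValueError("cell_meta references unknown samples")

    write_matrix(matrix, dir_path)
    cell_meta.to_csv(dir_path / "cells.tsv", sep="\t", index=False)
    sample_meta.to_csv(dir_path / "samples.tsv", sep="\t", index=False)
    if truth is not None:
        tdf = pd.DataFrame(
            {
                "cell_id": truth.cell_type.index,
                "fibre_type_true": truth.fibre_type.values,
                "pseudotime_true": truth.pseudotime.values,
            }
        )
        tdf.to_csv(dir_path / "truth.tsv", sep="\t", index=False)
    manifest = {
        "n_genes": int(len(matrix.genes)),
        "n_cells": int(len(matrix.cells)),
        "nnz": int(matrix.X.nnz),
        "seed": None if config is None else config.seed,
        "config": None if config is None else _config_echo(config),
        "files": sorted(p.name for p in dir_path.iterdir() if p.name != "manifest.json"),
    }
    with open(dir_path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_echo(config: SimConfig) -> dict:
    d = asdict(config)
    d["dispersion"] = {f"{ct}|{g}": v for (ct, g), v in config.dispersion.items()}
    return d


def read_fixture(dir_path):
    """Read back a fixture directory -> (CountMatrix, cell_meta, sample_meta, truth_df)."""
    dir_path = Path(dir_path)
    matrix = read_matrix(dir_path)
    cell_meta = pd.read_csv(dir_path / "cells.tsv", sep="\t")
    sample_meta = pd.read_csv(dir_path / "samples.tsv", sep="\t")
    truth_path = dir_path / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    return matrix, cell_meta, sample_meta, truth
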