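"""End-to-end validation studies exercising the pipeline on synthetic data.

Each function builds its own inputs with the generator, runs the relevant
pipeline stage and returns summary numbers: oracle agreement for the exact
Mann-Whitney test, QC/downsampling fidelity, power and null calibration of
the heterogeneity statistic, fibre-typing recovery, composition-model
recovery and LTSR calibration, trend-pipeline recovery, and determinism of
the seeded stages.  All randomness flows from the single seed argument.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from . import fibre_typing as ft
from . import heterogeneity as het
from . import synthetic as syn
from . import trajectory_trends as tt
from .io_qc import CountMatrix, QCThresholds, qc_filter
from .synthetic import SimConfig, _default_props

__all__ = [
    "mwu_oracle_agreement",
    "qc_toy_study",
    "downsampling_study",
    "noise_power_study",
    "fibre_recovery_study",
    "composition_recovery_study",
    "composition_null_calibration",
    "composition_backend_agreement",
    "trend_recovery_study",
    "determinism_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Mann-Whitney oracle battery


def _enumeration_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Direct 3-D enumeration over all C(n+m, n) group assignments."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y]).astype(float)
    N = n + m
    combs = list(itertools.combinations(range(N), n))
    xi = np.array(combs)
    mask = np.zeros((len(combs), N), dtype=bool)
    mask[np.arange(len(combs))[:, None], xi] = True
    xs = pooled[np.where(mask)[1]].reshape(len(combs), n)
    ys = pooled[np.where(~mask)[1]].reshape(len(combs), m)
    u_all = (xs[:, :, None] > ys[:, None, :]).sum(axis=(1, 2)) + 0.5 * (
        xs[:, :, None] == ys[:, None, :]
    ).sum(axis=(1, 2))
    U = float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())
    mid = n * m / 2.0
    p = float((np.abs(u_all - mid) >= abs(U - mid) - 1e-12).mean())
    return U, p


def mwu_oracle_agreement(seed: int, n_cases: int = 1000) -> dict:
    """Exact-mode U and p versus the enumeration oracle over random batteries."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n, m = rng.integers(1, 7, size=2)
        x = rng.integers(0, 8, size=n).astype(float)
        y = rng.integers(0, 8, size=m).astype(float)
        U, p = het.mann_whitney_u(x, y, mode="exact")
        U_o, p_o = _enumeration_oracle(x, y)
        agree += int(np.isclose(U, U_o) and np.isclose(p, p_o))
    toy_U, toy_p = het.mann_whitney_u([1, 2], [3, 4], mode="exact")
    return {
        "agreement_frac": agree / n_cases,
        "n_cases": n_cases,
        "toy_U": toy_U,
        "toy_p": toy_p,
    }


# ---------------------------------------------------------------------------
# QC and downsampling fidelity


def qc_toy_study() -> dict:
    """The printed 5-cell toy: totals/genes/mito fixed, strict thresholds."""
    import scipy.sparse as sp

    totals = [900, 1001, 1500, 2000, 3000]
    detected = [400, 501, 600, 700, 800]
    mito_pct = [1, 1, 6, 1, 1]
    n_genes = 1000
    dense = np.zeros((n_genes, 5), dtype=int)
    genes = ["MT-1"] + [f"g{i}" for i in range(n_genes - 1)]
    for j in range(5):
        mito = round(totals[j] * mito_pct[j] / 100)
        dense[0, j] = mito
        k = detected[j] - 1
        dense[1 : 1 + k, j] = 1
        dense[1, j] += totals[j] - mito - k
    m = CountMatrix(np.array(genes, dtype=object),
                    np.array([f"c{j+1}" for j in range(5)], dtype=object),
                    sp.csr_matrix(dense))
    out, _, report = qc_filter(m, thresholds=QCThresholds(1000, 500, 0.05))
    return {
        "retained_cells": list(out.cells),
        "n_retained": report["n_retained"],
        "expected": ["c2", "c4", "c5"],
        "correct": list(out.cells) == ["c2", "c4", "c5"],
    }


def downsampling_study(seed: int, n_reps: int = 100_000) -> dict:
    """Exact-total conservation plus the closed-form hypergeometric mean check."""
    import scipy.sparse as sp
    from scipy.stats import hypergeom

    rng = np.random.default_rng(seed)
    # conservation on a random matrix
    dense = rng.poisson(3.0, size=(40, 30))
    dense[:, dense.sum(axis=0) == 0] += 1
    m = CountMatrix(np.array([f"g{i}" for i in range(40)], dtype=object),
                    np.array([f"c{j}" for j in range(30)], dtype=object),
                    sp.csr_matrix(dense))
    target = int(m.cell_totals().min())
    from .io_qc import downsample_counts

    out = downsample_counts(m, target, rng)
    totals_exact = bool((out.cell_totals() == target).all())

    # cell [8, 2], target 5: mean of the first entry is 5*8/10 = 4
    draws = rng.multivariate_hypergeometric([8, 2], 5, size=n_reps)
    dist = hypergeom(10, 8, 5)
    dev_se = abs(draws[:, 0].mean() - dist.mean()) / (dist.std() / np.sqrt(n_reps))
    return {
        "totals_exact": totals_exact,
        "target": target,
        "mean_first_entry": float(draws[:, 0].mean()),
        "expected_mean": float(dist.mean()),
        "deviation_in_se": float(dev_se),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Heterogeneity statistic: power and null calibration


def _noise_atlas(seed: int, phi_adult: float, phi_old: float,
                 cells_per_group: int = 300, n_genes: int = 300):
    cfg = SimConfig(
        n_samples_per_group=3,
        n_cells_per_sample=cells_per_group // 3,
        n_genes=n_genes,
        cell_type_props={"MuSC": 1.0},
        age_effects={},
        dispersion={("MuSC", "adult"): phi_adult, ("MuSC", "old"): phi_old},
        pseudotime_trend_genes={},
        seed=seed,
    )
    return syn.generate_atlas(cfg)


def noise_power_study(
    seed: int,
    n_power: int = 100,
    n_null: int = 200,
    phi: float = 0.3,
    cells_per_group: int = 300,
) -> dict:
    """Rejection rates of the per-cell-type noise test.

    Power arm: phi_old = 2 * phi_adult, alpha = 0.01.  Null arm: equal
    dispersion, alpha = 0.05 (should reject at ~ the nominal rate).
    """
    seeds = _child_seeds(seed, n_power + n_null)
    power_hits = 0
    for s in seeds[:n_power]:
        m, cm, sm, _ = _noise_atlas(s, phi, 2 * phi, cells_per_group)
        res = het.noise_per_cell(m, cm, sm, "MuSC", n_max=cells_per_group, seed=s)
        power_hits += int(res.p < 0.01 and res.median_old > res.median_adult)
    null_hits = 0
    for s in seeds[n_power:]:
        m, cm, sm, _ = _noise_atlas(s, phi, phi, cells_per_group)
        res = het.noise_per_cell(m, cm, sm, "MuSC", n_max=cells_per_group, seed=s)
        null_hits += int(res.p < 0.05)
    return {
        "power_reject_frac": power_hits / n_power,
        "n_power": n_power,
        "null_reject_frac": null_hits / n_null,
        "n_null": n_null,
        "cells_per_group": cells_per_group,
    }


# ---------------------------------------------------------------------------
# Fibre typing


def fibre_recovery_study(seed: int, n_myonuclei: int = 5000) -> dict:
    """Pure-class accuracy and hybrid-or-parent recovery on a marker_effect=4 atlas."""
    cfg = SimConfig(
        n_samples_per_group=5,
        n_cells_per_sample=n_myonuclei // 10,
        n_genes=800,
        cell_type_props={"type_I_myonuclei": 0.45, "type_II_myonuclei": 0.55},
        age_effects={},
        default_dispersion=0.3,
        marker_effect=4.0,
        hybrid_frac=0.10,
        seed=seed,
    )
    from .io_qc import normalize_log1p

    m, cm, sm, truth = syn.generate_atlas(cfg)
    nm = normalize_log1p(m)
    ms = ft.compute_module_scores(nm, seed=seed)
    calls = ft.classify_fibre_types(ms).set_index("cell_id")
    true = truth.fibre_type.loc[calls.index]
    pure = true.isin(["I", "IIA", "IIX"])
    acc = float((calls.loc[pure, "final_class"] == true[pure]).mean())
    parents = {"hybrid I/IIA": {"hybrid I/IIA", "I", "IIA"},
               "hybrid IIA/IIX": {"hybrid IIA/IIX", "IIA", "IIX"}}
    hyb = true[true.str.startswith("hybrid")]
    hyb_ok = float(np.mean([calls.loc[c, "final_class"] in parents[t]
                            for c, t in hyb.items()]))
    confusion = pd.crosstab(true, calls["final_class"])
    return {
        "pure_accuracy": acc,
        "hybrid_or_parent_frac": hyb_ok,
        "n_myonuclei": int(len(calls)),
        "n_pure": int(pure.sum()),
        "n_hybrid": int(len(hyb)),
        "confusion": confusion,
    }


# ---------------------------------------------------------------------------
# Composition model


def composition_recovery_study(seed: int, n_samples_per_group: int = 20) -> dict:
    """Recovery of a grand-mean-relative old-vs-adult log FC of ln 2 on one type."""
    ln2 = float(np.log(2))
    props = _default_props()
    C = len(props)
    effects = {ct: -ln2 / (C - 1) for ct in props}
    effects["MuSC"] = ln2
    cfg = SimConfig(n_samples_per_group=n_samples_per_group,
                    n_cells_per_sample=3000, n_genes=120,
                    age_effects=effects, pseudotime_trend_genes={}, seed=seed)
    _, cm, sm, _ = syn.generate_atlas(cfg)
    cc = comp.build_counts(cm, sm)
    post = comp.fit_poisson_glmm(cc, ["age_group", "sex"], inference="laplace")
    row = post.level_contrast("age_group", "old", "adult").set_index(
        "cell_type").loc["MuSC"]
    return {
        "true_log_fc": ln2,
        "estimated_log_fc": float(row["mean"]),
        "ci_low": float(row["ci_low"]),
        "ci_high": float(row["ci_high"]),
        "covered": bool(row["ci_low"] <= ln2 <= row["ci_high"]),
        "sign_correct": bool(row["mean"] > 0),
    }


def composition_null_calibration(seed: int, n_reps: int = 200) -> dict:
    """Fraction of age-effect coefficients with LTSR > 0.9 under a null."""
    props = {"MuSC": .15, "FAP": .2, "EC": .15, "myeloid": .1,
             "pericyte": .1, "SMC": .1, "lymphoid": .1, "adipocyte": .1}
    n_hi = n_tot = 0
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(n_samples_per_group=10, n_cells_per_sample=300,
                        n_genes=80, cell_type_props=props, age_effects={},
                        pseudotime_trend_genes={}, seed=s)
        _, cm, sm, _ = syn.generate_atlas(cfg)
        post = comp.fit_poisson_glmm(comp.build_counts(cm, sm), ["age_group"],
                                     inference="laplace")
        s_tab = comp.summarize_ltsr(post)
        n_hi += int((s_tab["ltsr"] > 0.9).sum())
        n_tot += len(s_tab)
    return {"frac_ltsr_gt_090": n_hi / n_tot, "n_coefficients": n_tot,
            "n_reps": n_reps}


def composition_backend_agreement(seed: int) -> dict:
    """Max |Laplace - MCMC| posterior-mean log fold change on a test fixture."""
    ln2 = float(np.log(2))
    props = _default_props()
    C = len(props)
    effects = {ct: -ln2 / (C - 1) for ct in props}
    effects["MuSC"] = ln2
    cfg = SimConfig(n_samples_per_group=10, n_cells_per_sample=500, n_genes=150,
                    age_effects=effects, pseudotime_trend_genes={}, seed=seed)
    _, cm, sm, _ = syn.generate_atlas(cfg)
    cc = comp.build_counts(cm, sm)
    pl = comp.fit_poisson_glmm(cc, ["age_group"], inference="laplace")
    pm = comp.fit_poisson_glmm(cc, ["age_group"], inference="mcmc", seed=seed,
                               mcmc_draws=3000, mcmc_burn=4000, mcmc_thin=10)
    a = comp.summarize_ltsr(pl).set_index(["cell_type", "level"])["log_fc"]
    b = comp.summarize_ltsr(pm).set_index(["cell_type", "level"])["log_fc"]
    return {"max_abs_diff_log_fc": float(np.abs(a - b).max()),
            "mcmc_accept_rate": float(pm.diagnostics["accept_rate"])}


# ---------------------------------------------------------------------------
# Trend pipeline


def trend_recovery_study(seed: int) -> dict:
    """Two-archetype k-means recovery, age occupancy trend, abrupt-vs-progressive."""
    from scipy.stats import spearmanr
    from sklearn.metrics import adjusted_rand_score

    from .io_qc import normalize_log1p

    cfg = SimConfig(
        n_samples_per_group=4, n_cells_per_sample=2000, n_genes=450,
        cell_type_props={"type_I_myonuclei": 1.0}, age_effects={},
        hybrid_frac=0.0,
        pseudotime_trend_genes={"monotone_up": 60, "monotone_down": 60,
                                "late_abrupt_up": 60, "flat": 60},
        seed=seed,
    )
    m, cm, sm, truth = syn.generate_atlas(cfg)
    nm = normalize_log1p(m)
    pt = truth.pseudotime.loc[m.cells].to_numpy()
    bins = tt.bin_pseudotime(pt, n_bins=100, cell_ids=m.cells)
    bm = tt.aggregate_bins(nm, bins)

    updown = [g for g, a in truth.gene_archetype.items()
              if a in ("monotone_up", "monotone_down")]
    tc = tt.cluster_gene_trends(bm, updown, k=2, seed=seed)
    ari = float(adjusted_rand_score(
        [truth.gene_archetype[g] for g in tc.genes], tc.labels))

    groups = cm.merge(sm[["sample_id", "age_group"]],
                      on="sample_id")["age_group"].to_numpy()
    props = tt.group_proportion_per_bin(bins, groups)
    rho = float(spearmanr(props.index.to_numpy(),
                          props["prop_old"].to_numpy()).statistic)

    mix = [g for g, a in truth.gene_archetype.items()
           if a in ("monotone_up", "late_abrupt_up")]
    tc2 = tt.cluster_gene_trends(bm, mix, k=2, seed=seed)
    jumps = {}
    for k in (1, 2):
        arch = truth.gene_archetype[next(iter(set(tc2.cluster_members(k))))]
        jumps[arch] = float(np.abs(np.diff(tc2.centroids[k - 1])).max())
    return {
        "updown_ari": ari,
        "old_frac_spearman": rho,
        "abrupt_max_jump": jumps.get("late_abrupt_up", float("nan")),
        "progressive_max_jump": jumps.get("monotone_up", float("nan")),
        "n_cells": int(len(m.cells)),
    }


# ---------------------------------------------------------------------------
# Determinism / round trips


def determinism_study(seed: int) -> dict:
    """Byte-identical seeded outputs and lossless MatrixMarket round trips."""
    import hashlib

    def digest(p: Path) -> str:
        return hashlib.md5(p.read_bytes()).hexdigest()

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        hashes = []
        for sub in ("a", "b"):
            cfg = SimConfig(n_samples_per_group=2, n_cells_per_sample=60,
                            n_genes=250, seed=seed)
            m, cm, sm, truth = syn.generate_atlas(cfg)
            syn.write_fixture(m, cm, sm, truth, tmp / sub, config=cfg)
            hashes.append({f: digest(tmp / sub / f)
                           for f in ("matrix.mtx", "cells.tsv", "samples.tsv",
                                     "truth.tsv")})
        byte_identical = hashes[0] == hashes[1]
        m2, *_ = syn.read_fixture(tmp / "a")
        lossless = bool((m2.X != m.X).nnz == 0 and
                        list(m2.genes) == list(m.genes))
        # a seeded pipeline stage reproduces exactly
        r1 = het.noise_per_cell(m, cm, sm, "type_II_myonuclei", n_max=50,
                                seed=seed)
        r2 = het.noise_per_cell(m, cm, sm, "type_II_myonuclei", n_max=50,
                                seed=seed)
        stage_reproducible = bool(r1.per_cell.equals(r2.per_cell))
    return {
        "fixture_byte_identical": byte_identical,
        "round_trip_lossless": lossless,
        "noise_stage_reproducible": stage_reproducible,
    }
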