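"""Synthetic atlas generator: structure, null behaviour, dispersion, fixtures."""

import hashlib
import json

import numpy as np
import pytest
from scipy.stats import ttest_ind

import agemyo as am
from agemyo.synthetic import _default_props


def _md5(path):
    return hashlib.md5(path.read_bytes()).hexdigest()


class TestConfigValidation:
    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="sum"):
            am.SimConfig(cell_type_props={"A": 0.5, "B": 0.4}).validate()

    def test_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            am.SimConfig(n_cells_per_sample=0).validate()

    def test_marker_effect_must_exceed_one(self):
        with pytest.raises(ValueError, match="marker_effect"):
            am.SimConfig(marker_effect=1.0).validate()

    def test_negative_dispersion(self):
        with pytest.raises(ValueError, match="phi"):
            am.SimConfig(dispersion={("MuSC", "old"): -0.1}).validate()


class TestAtlasStructure:
    def test_conservation_and_truth_alignment(self, small_atlas):
        cfg, m, cm, smeta, truth = small_atlas
        per_sample = cm.groupby("sample_id").size()
        assert (per_sample == cfg.n_cells_per_sample).all()
        assert len(smeta) == 2 * cfg.n_samples_per_group
        # every truth cell appears exactly once in the metadata
        assert truth.cell_type.index.is_unique
        assert set(truth.cell_type.index) == set(cm["cell_id"])

    def test_mito_genes_prefixed(self, small_atlas):
        cfg, m, *_ = small_atlas
        n_mito = int(np.ceil(0.01 * cfg.n_genes))
        assert sum(g.startswith("MT-") for g in m.genes) == n_mito

    def test_marker_panels_present(self, small_atlas):
        _, m, *_ = small_atlas
        panel_genes = {g for p in am.builtin_panels().values() for g in p.genes}
        assert panel_genes.issubset(set(m.genes))

    def test_proportions_converge(self):
        # at n = 50,000 cells the empirical per-type proportions sit within
        # 3 multinomial SEs of the configured ones (null age effects)
        props = {"A_t": 0.5, "B_t": 0.3, "C_t": 0.2}
        cfg = am.SimConfig(n_samples_per_group=5, n_cells_per_sample=5000,
                           n_genes=250, cell_type_props=props, age_effects={},
                           pseudotime_trend_genes={}, seed=60)
        _, cm, _, _ = am.generate_atlas(cfg)
        n = len(cm)
        emp = cm["cell_type"].value_counts(normalize=True)
        for ct, p in props.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(emp[ct] - p) < 3 * se

    def test_null_age_effects_equal_group_proportions(self):
        cfg = am.SimConfig(n_samples_per_group=6, n_cells_per_sample=2000,
                           n_genes=250, age_effects={},
                           pseudotime_trend_genes={}, seed=61)
        _, cm, smeta, _ = am.generate_atlas(cfg)
        grp = cm.merge(smeta[["sample_id", "age_group"]], on="sample_id")
        for ct, p in cfg.cell_type_props.items():
            counts = grp.groupby("age_group")["cell_type"].apply(
                lambda s: (s == ct).mean())
            n_per_group = len(grp) / 2
            se = np.sqrt(p * (1 - p) / n_per_group)
            assert abs(counts["old"] - counts["adult"]) < 3 * np.sqrt(2) * se

    def test_unit_marker_effect_gives_no_signal(self):
        # marker_effect -> 1 is invalid by contract; 1 + 1e-9 is the no-signal
        # limit: per-nucleus mean marker expression indistinguishable
        cfg = am.SimConfig(
            n_samples_per_group=2, n_cells_per_sample=300, n_genes=500,
            cell_type_props={"type_I_myonuclei": 0.5, "type_II_myonuclei": 0.5},
            age_effects={}, marker_effect=1.0 + 1e-9, hybrid_frac=0.0,
            pseudotime_trend_genes={}, seed=62,
        )
        m, cm, _, truth = am.generate_atlas(cfg)
        nm = am.normalize_log1p(m)
        panel = am.builtin_panels()["type_I"]
        rows = [list(m.genes).index(g) for g in panel.genes]
        means = np.asarray(nm.X[rows, :].mean(axis=0)).ravel()
        ft = truth.fibre_type.loc[m.cells]
        t = ttest_ind(means[(ft == "I").to_numpy()],
                      means[(ft != "I").to_numpy()])
        assert t.pvalue > 0.01


class TestDispersionStructure:
    def test_variance_mean_ratio_tracks_phi(self):
        # phi_old = 2 * phi_adult: per-gene var/mean larger in old, matching a
        # Monte-Carlo negative-binomial oracle at the same parameters
        phi_a, phi_o = 0.3, 0.6
        cfg = am.SimConfig(n_samples_per_group=3, n_cells_per_sample=400,
                           n_genes=250, cell_type_props={"MuSC": 1.0},
                           age_effects={},
                           dispersion={("MuSC", "adult"): phi_a,
                                       ("MuSC", "old"): phi_o},
                           libsize_lognormal=(8.0, 1e-6),
                           pseudotime_trend_genes={}, seed=63)
        m, cm, smeta, _ = am.generate_atlas(cfg)
        grp = cm.merge(smeta[["sample_id", "age_group"]], on="sample_id")
        nuclear = np.array([not g.startswith("MT-") for g in m.genes])
        X = m.X.toarray()[nuclear]  # mito counts vary with the Beta fraction
        ratios = {}
        for g in ("adult", "old"):
            cols = (grp["age_group"] == g).to_numpy()
            sub = X[:, cols]
            mu = sub.mean(axis=1)
            keep = mu > 1
            ratios[g] = float((sub.var(axis=1, ddof=1)[keep] / mu[keep]).mean())
        assert ratios["old"] > ratios["adult"]

        # Monte-Carlo oracle: 1e5 NB deviates at a representative mean
        rng = np.random.default_rng(99)
        mu = 5.0
        for phi, emp in ((phi_a, ratios["adult"]), (phi_o, ratios["old"])):
            lam = rng.gamma(1 / phi, phi * mu, size=100_000)
            draws = rng.poisson(lam)
            oracle = draws.var() / draws.mean()  # ~ 1 + phi * mu
            assert np.isclose(oracle, 1 + phi * mu, rtol=0.05)
        # empirical ratio gap is in the direction and rough size the oracle
        # predicts (means vary per gene, so compare ordering only)
        assert ratios["old"] / ratios["adult"] > 1.2

    def test_phi_zero_is_poisson(self):
        cfg = am.SimConfig(n_samples_per_group=2, n_cells_per_sample=300,
                           n_genes=250, cell_type_props={"MuSC": 1.0},
                           age_effects={}, default_dispersion=0.0,
                           libsize_lognormal=(8.0, 1e-6),
                           pseudotime_trend_genes={}, seed=64)
        m, *_ = am.generate_atlas(cfg)
        nuclear = np.array([not g.startswith("MT-") for g in m.genes])
        X = m.X.toarray()[nuclear]
        mu = X.mean(axis=1)
        keep = mu > 2
        vmr = X.var(axis=1, ddof=1)[keep] / mu[keep]
        assert abs(vmr.mean() - 1.0) < 0.1


class TestGeneScores:
    def test_zero_rate_gives_zero_matrix(self):
        cfg = am.SimConfig(n_samples_per_group=2, n_cells_per_sample=20,
                           n_genes=250, cell_type_props={"MuSC": 1.0},
                           age_effects={}, libsize_lognormal=(-30.0, 1e-9),
                           pseudotime_trend_genes={}, seed=65)
        gs, *_ = am.generate_gene_scores(cfg)
        from agemyo.heterogeneity import round_half_away_from_zero
        assert round_half_away_from_zero(gs.X).sum() == 0

    def test_rounding_sum_identity(self):
        from agemyo.heterogeneity import round_half_away_from_zero
        cfg = am.SimConfig(n_samples_per_group=2, n_cells_per_sample=30,
                           n_genes=250, cell_type_props={"MuSC": 1.0},
                           age_effects={}, pseudotime_trend_genes={}, seed=66)
        gs, *_ = am.generate_gene_scores(cfg)
        r = round_half_away_from_zero(gs.X)
        assert r.sum() == int(np.sum(r))  # exact integer arithmetic


class TestFixtureIO:
    def test_round_trip_and_manifest(self, tmp_path, small_atlas):
        cfg, m, cm, smeta, truth = small_atlas
        manifest = am.write_fixture(m, cm, smeta, truth, tmp_path, config=cfg)
        assert manifest["seed"] == cfg.seed
        m2, cm2, sm2, truth_df = am.read_fixture(tmp_path)
        assert (m2.X != m.X).nnz == 0
        assert list(m2.genes) == list(m.genes)
        assert len(truth_df) == len(cm)
        saved = json.loads((tmp_path / "manifest.json").read_text())
        assert saved["n_cells"] == len(m.cells)

    def test_seeded_runs_byte_identical(self, tmp_path):
        dirs = [tmp_path / "a", tmp_path / "b"]
        for d in dirs:
            cfg = am.SimConfig(n_samples_per_group=2, n_cells_per_sample=40,
                               n_genes=250, seed=4242)
            m, cm, smeta, truth = am.generate_atlas(cfg)
            am.write_fixture(m, cm, smeta, truth, d, config=cfg)
        for name in ("matrix.mtx", "cells.tsv", "samples.tsv", "truth.tsv"):
            assert _md5(dirs[0] / name) == _md5(dirs[1] / name)

    def test_toy_header_counts_nonzeros(self, tmp_path):
        from conftest import toy_matrix
        m = toy_matrix([[1, 2], [0, 3], [4, 0]])
        am.write_matrix(m, tmp_path)
        header = [l for l in (tmp_path / "matrix.mtx").read_text().splitlines()
                  if not l.startswith("%")][0]
        assert header.split() == ["3", "2", "4"]

    def test_id_mismatch_raises(self, tmp_path, small_atlas):
        _, m, cm, smeta, truth = small_atlas
        bad = cm.copy()
        bad.loc[bad.index[0], "cell_id"] = "rogue"
        with pytest.raises(ValueError, match="ids"):
            am.write_fixture(m, bad, smeta, truth, tmp_path)


class TestNaiveMarkerRecovery:
    def test_argmax_classifier_learns_fixture(self, myo_atlas):
        # establishes learnability before testing the real classifier
        _, m, nm, cm, _, truth = myo_atlas
        panels = am.builtin_panels()
        per_class = {}
        gidx = {g: i for i, g in enumerate(nm.genes)}
        for ft, pname in (("I", "type_I"), ("IIA", "type_IIA"),
                          ("IIX", "type_IIX")):
            rows = [gidx[g] for g in panels[pname].genes]
            per_class[ft] = np.asarray(nm.X[rows, :].mean(axis=0)).ravel()
        score = np.vstack([per_class[c] for c in ("I", "IIA", "IIX")])
        pred = np.array(["I", "IIA", "IIX"], dtype=object)[score.argmax(axis=0)]
        ft = truth.fibre_type.loc[nm.cells].to_numpy()
        pure = np.isin(ft, ["I", "IIA", "IIX"])
        assert (pred[pure] == ft[pure]).mean() >= 0.95
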