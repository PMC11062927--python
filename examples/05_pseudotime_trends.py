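"""Bin a degeneration pseudotime and cluster gene trends along it.

Given a per-cell pseudotime (an input — trajectory inference itself is out of
scope), cells are split into 100 equal-count bins; we then track per-bin
age-group occupancy, cluster z-scored gene trends with k-means, and follow a
marker-panel score along the trajectory.
"""

import numpy as np

import agemyo as am

cfg = am.SimConfig(
    n_samples_per_group=4, n_cells_per_sample=1000, n_genes=450,
    cell_type_props={"type_I_myonuclei": 1.0}, age_effects={}, hybrid_frac=0.0,
    pseudotime_trend_genes={"monotone_up": 60, "monotone_down": 60,
                            "late_abrupt_up": 60, "flat": 60},
    seed=55,
)
matrix, cell_meta, sample_meta, truth = am.generate_atlas(cfg)
nm = am.normalize_log1p(matrix)

pt = truth.pseudotime.loc[matrix.cells].to_numpy()
bins = am.bin_pseudotime(pt, n_bins=100, cell_ids=matrix.cells)
bin_matrix = am.aggregate_bins(nm, bins)

groups = cell_meta.merge(sample_meta[["sample_id", "age_group"]],
                         on="sample_id")["age_group"].to_numpy()
occ = am.group_proportion_per_bin(bins, groups)
print(f"old fraction: first 10 bins {occ['prop_old'].iloc[:10].mean():.2f}, "
      f"last 10 bins {occ['prop_old'].iloc[-10:].mean():.2f} "
      "(older nuclei crowd the late trajectory)")

genes = am.select_variable_genes(bin_matrix, n_top=200)
tc = am.cluster_gene_trends(bin_matrix, genes, k=4, seed=0)
for k in range(1, 5):
    members = tc.cluster_members(k)
    archs = {truth.gene_archetype.get(g, "background") for g in members}
    jump = np.abs(np.diff(tc.centroids[k - 1])).max()
    print(f"cluster {k}: {len(members)} genes, archetypes {sorted(archs)}, "
          f"max successive-bin jump {jump:.2f}")
print("The late-abrupt cluster shows a much larger single-bin jump than the "
      "monotone (progressive) clusters.  Flat/background genes have no signal, "
      "so their z-scored trends are amplified noise — jumpy but structureless.")
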