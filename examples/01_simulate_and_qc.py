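"""Simulate a small ageing-muscle atlas, write it to disk, and QC-filter it.

The generator emits a sparse gene x cell count matrix with 15 cell types,
fibre-typed myonuclei, two age groups and per-sample covariates; the QC stage
keeps cells with >1,000 UMIs, >500 detected genes and <5% mitochondrial reads.
"""

from pathlib import Path

import agemyo as am

cfg = am.SimConfig(n_samples_per_group=3, n_cells_per_sample=500, n_genes=800,
                   seed=7)
matrix, cell_meta, sample_meta, truth = am.generate_atlas(cfg)

out = Path("scratch_example_atlas")
manifest = am.write_fixture(matrix, cell_meta, sample_meta, truth, out, config=cfg)
print(f"wrote {manifest['n_genes']} genes x {manifest['n_cells']} cells "
      f"({manifest['nnz']} nonzeros) to {out}/")

filtered, meta_f, report = am.qc_filter(matrix, cell_meta, am.QCThresholds())
print(f"QC: {report['n_input']} cells in, {report['n_retained']} retained "
      f"(failed UMI: {report['fail_umi']}, genes: {report['fail_genes']}, "
      f"mito: {report['fail_mito']})")
# The retained fraction reflects the simulated library-size and mito-fraction
# distributions; every retained cell satisfies all three strict bounds.
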