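# Methods

This note documents the models and procedures implemented in `agemyo`, the
defaults they use, the design choices that were genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Quality control and normalisation

Cells are retained when total UMIs > 1,000 AND detected genes (count > 0)
> 500 AND mitochondrial fraction < 5%. All three bounds are strict
inequalities, so boundary cells (exactly 1,000 UMIs) are removed.
Mitochondrial genes are recognised by the `MT-` prefix. Normalisation scales
each cell to `target_sum` total counts (default 10,000, the de-facto
community standard; the underlying protocol states total-count normalisation
without a scale) and applies log1p. Zero counts map to zero, and the
transform is exactly invertible given the cell totals.

## Downsampling primitives

`downsample_cells` is a seeded simple random sample without replacement;
groups at or below the cap are returned whole. `downsample_counts` replaces
each cell's count vector with a multivariate-hypergeometric draw of exactly
the target total from its observed molecules. Hypergeometric (without
replacement) sampling rather than binomial thinning was chosen because the
matched-depth comparison requires *exactly* equal totals per cell; it also
guarantees no entry exceeds its original value. The common target for a
two-group comparison is the minimum per-cell total across both groups'
sampled cells — the maximal depth at which every cell can be matched.
Depth equalisation is performed per cell (not merely per group total); the
group-total-only reading of depth matching would leave per-cell depth
variation that the distance statistic confounds with heterogeneity.

## Transcriptional and epigenetic heterogeneity

Pipeline for one cell type: (i) downsample each age group to
min(300, group size) cells; (ii) equalise the two groups to the smaller
count; (iii) downsample every retained cell to the common minimum total;
(iv) log-normalise; (v) select invariant genes; (vi) compute each cell's
Euclidean distance over invariant genes to the centroid of its own
(cell type × age group); (vii) compare groups with a two-tailed
Mann–Whitney U-test.

Invariant genes: zero-mean genes are excluded; the remainder are ranked by
mean (ties by gene id) into 10 near-equal blocks — block size ⌊G/10⌋ with the
remainder assigned to the highest-expression blocks — and within each block
the ⌈10% · block size⌉ genes with smallest CV (sample sd / mean, computed on
normalised values) are kept. Selection is joint across the pooled matched
matrix of both groups, so both groups are scored against the same gene set.

"Distance between each cell" is implemented as distance to the own-group
centroid, which yields the per-cell statistic the box-plot comparison needs;
mean pairwise distance to the other cells of the group is available via
`mode="pairwise"`. Distances are computed on log-normalised, depth-matched
counts — raw-count distances would be dominated by residual depth even after
matching.

The randomness of the downsampling steps is keyed on the *cell ids* of each
group (via a CRC of the sorted ids mixed into the seed), not on the group
label or iteration order. Consequently swapping the adult/old labels leaves
every distance unchanged and maps U to nm − U, which the tests assert.

The epigenetic arm rounds a nonnegative gene-activity-score matrix to
integers (half away from zero — a stated, locale-independent rule) and runs
the identical pipeline.

### Mann–Whitney U

U = Σ<sub>ij</sub> [x<sub>i</sub> > y<sub>j</sub>] + ½[x<sub>i</sub> =
y<sub>j</sub>]. Exact mode enumerates all C(n+m, n) assignments of the
pooled values (ties handled naturally by enumeration) and takes the
two-sided p as the fraction of assignments at least as extreme, measured by
|U − nm/2|. `auto` uses exact when n + m ≤ 12, otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity correction.
The exact path is validated against an independent brute-force enumeration
oracle and, in tie-free cases, against `scipy.stats.mannwhitneyu`.

## Fibre typing

Module score = mean normalised expression of the panel genes − mean of
control genes, where each panel gene contributes `n_ctrl` controls sampled
from its average-expression bin (`n_bins` rank bins over all genes; without
replacement when the bin is large enough, with replacement otherwise).
Defaults `n_bins = 25`, `n_ctrl = 100` follow the widely used defaults of
this scoring scheme. Controls are drawn from the full bin, so a panel gene
can appear among its own controls; with realistic panel/bin ratios this
attenuates a pure shift of size k to roughly k·(1 − panel/bin), which is
negligible at scale and exercised explicitly in the tests.

Scores are z-standardised across cells per panel before thresholding, making
the two decision thresholds dimensionless: `tau_unclassified = 0` (a nucleus
must score above the cellwise mean on some panel to be classified) and
`delta_hybrid = 0.5` (hybrids are nuclei whose two parent panels are both
above threshold and within half a standard deviation of each other). The
hybrid test precedes the argmax — otherwise hybrids would be unreachable.
Argmax ties break toward the more oxidative class (I at tier 1, IIA at
tier 2); ties have measure ~0 on real scores. The classifier is invariant to
any per-panel affine rescaling applied before standardisation.

Because the upstream study states the decision tree but not its cutoffs,
published proportion panels can only be matched qualitatively; the tests
therefore assert recovery on synthetic truth (≥90% pure-class accuracy,
≥70% of hybrids called hybrid-or-parent at the defaults) rather than
numerical equality with any published figure.

## Composition model

y<sub>s,c</sub> ~ Poisson(λ<sub>s,c</sub>) with
log λ<sub>s,c</sub> = log N<sub>s</sub> + μ + α<sub>c</sub> +
Σ<sub>f</sub> B<sub>f</sub>[f(s), c] + u<sub>s</sub>.
The offset log N<sub>s</sub> makes the model compositional (doubling all
counts leaves effects unchanged; asserted as a regression test). Reported
effects are the doubly centred interactions — sum-to-zero over cell types
within each level and over levels within each cell type — i.e. log fold
changes relative to the grand mean. `level_contrast` additionally reports
between-level contrasts (e.g. old − adult) per cell type.

Priors: μ ~ N(0, 5²), α<sub>c</sub> ~ N(0, 3²), u<sub>s</sub> ~ N(0, σ²)
with σ ~ Half-Normal(1), and an adaptive-shrinkage prior on each factor's
interactions: B<sub>f</sub> = τ<sub>f</sub> · B<sub>raw</sub>,
B<sub>raw</sub> ~ N(0, 1), τ<sub>f</sub> ~ Half-Normal(1.5). The hierarchical
scale is essential for calibration: with a fixed weak prior the LTSR behaves
like a flat-prior z-test (≈20% of null coefficients reach LTSR > 0.9),
whereas a learned τ<sub>f</sub> collapses under a null factor and drives the
LTSR toward 0.5, while a factor with real effects learns a wider scale and
keeps power. Under the default study conditions the null rate of
LTSR > 0.9 is ≈5%.

Inference. The default backend is empirical-Bayes Laplace in the style of
lme4/glmmTMB: for fixed scales φ = (log τ<sub>f</sub>…, log σ) the linear
parameters are a smooth Poisson-Gaussian problem solved by damped Newton
iterations; φ is optimised by Nelder–Mead on the Laplace-approximate marginal
likelihood (including the Half-Normal scale priors); the reported posterior
is the Gaussian conditional at φ̂. A joint MAP over scales is *not* used —
the mode of a hierarchical scale parameter ignores the marginalisation and
fails to shrink. The MCMC backend samples the full joint posterior in a
non-centred parametrization (which keeps the density bounded near σ, τ → 0)
with a random-walk Metropolis sampler preconditioned by the Laplace
covariance and burn-in scale adaptation toward 25% acceptance; it serves as
an independent cross-check (posterior means within 0.1 on the log scale on
the test fixture) and for small problems.

LTSR = max(P(β>0), P(β<0)) ∈ [0.5, 1]; under the Gaussian approximation this
is Φ(|mean|/sd). Fold change = exp(posterior mean); the credible interval is
reported on the log scale. `simple_proportions` provides the plain
count/total alternative per sample or per dataset (modality).

Identifiability note: with a fixed per-sample total, only grand-mean-relative
effects are identified. A simulated "log FC of ln 2 on one cell type" is
therefore configured as centred truth (+ln 2 on the target, −ln 2/(C−1) on
the rest) so that the estimand equals ln 2 exactly; recovery is asserted as
sign correctness plus 95%-interval coverage.

## Pseudotime trends

Pseudotime is an input (trajectory inference is out of scope; the generator
provides ground truth). Cells are ranked (ties by cell id) and split into
100 equal-count bins — equal-count rather than equal-width guarantees
non-empty bins and makes the whole pipeline invariant under any strictly
monotone transform of pseudotime; the division remainder goes to the
earliest bins. Bin × gene means feed: variable-gene selection (variance of
the binned trend, descending, ties by id; default top 4,000 — computed at
bin level, which denoises cell-level variance), k-means over per-gene
z-scored trends (k-means++ with `n_init = 10` restarts, defaults k = 10),
per-bin age-group occupancy, and bin-averaged module scores. Fitted
centroids are renumbered by the bin of their peak so cluster labels are
deterministic and trajectory-ordered.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes: 15 cell types
with baseline proportions dominated by type I/II myonuclei; per-cell-type
old-vs-adult abundance tilts exp(effect) applied to the multinomial
proportions (identified up to the compositional constant); negative-binomial
counts (mean μ, dispersion φ, Var = μ + φμ²; φ = 0 degenerates to Poisson,
default φ = 0.3 — typical snRNA-seq overdispersion) with lognormal library
sizes (median ≈ 3,000 UMIs) and Beta(2, 98) mitochondrial fractions routed
to the `MT-` genes (the first ⌈1%⌉ of gene ids). Myonuclei carry the four
shipped marker panels: fibre type I elevates the type I panel, IIA the
type II + IIA panels, IIX the type II + IIX panels, each `marker_effect`-fold
(default 4); hybrids are 50/50 mixtures of the parent mean vectors (matching
their biology of co-expressing two myosin genes). Marker genes share a
common baseline expression — they are uniformly well-expressed sarcomeric
genes, and a shared baseline keeps the panels comparable so the fixture is
learnable by construction (a naive argmax-of-panel-means classifier reaches
≥95% on pure classes, asserted before any test of the real classifier).

Myofibre nuclei receive a latent degeneration pseudotime: Beta(1.5, 3) in
adults, Beta(3, 1.5) in old — old nuclei crowd the late trajectory. Four
trend archetypes modulate dedicated genes multiplicatively: monotone up
(0.5 + 2t), monotone down (2.5 − 2t), late-abrupt up (logistic at t = 0.8
with width ≈ 0.05, i.e. a few bins of a 100-bin ordering — genuinely abrupt,
which is the point of the progressive-vs-abrupt contrast), and flat. Gene
activity scores (the epigenetic arm's input) are gamma with the same mean
and dispersion structure, mean μ and variance φμ².

Samples carry sex / ethnicity / batch / modality labels assigned round-robin
and ages spread over 20–46 (adult) and 74–95 (old) years. Everything is
drawn from a single seeded generator, so identical configs give byte-identical
fixtures (asserted at file level).

What the generator does **not** emulate: doublets, ambient RNA, batch
*expression* effects (batch is a label only), cell-type-specific library
sizes, gene–gene correlation beyond the marker/trend programs, and real
marker redundancy or dropout structure. Passing tests therefore establish
that the statistics detect the effects they target at realistic effect sizes
and sample sizes — not that real tissue meets the generator's assumptions.

## Problem sizes and numerical choices

Validation studies run at desk scale, chosen so the statistics operate in
their intended regime: noise power/calibration at 300 cells per group over
100/200 replicates; fibre recovery on 5,000 myonuclei; composition recovery
at 20 samples per group with 3,000 cells per sample (deep enough that
empirical-Bayes shrinkage bias is small relative to the credible interval);
null calibration over 200 replicate fits; trend recovery on 16,000 cells
(160 per bin) with 60 genes per archetype so bin-level standard error is
small against the abrupt jump. Tolerances: exact Mann–Whitney agreement is
exact; stochastic checks use 3-SE bands or binomial 99% confidence bounds at
their stated replicate counts. Degenerate inputs (empty groups, zero-total
cells, absent panels, single-level factors) raise or warn as documented on
each function.

## Known limitations

- The noise statistic conflates any residual mean-expression shift between
  groups with dispersion differences; the invariant-gene selection mitigates
  but does not eliminate this.
- Empirical-Bayes Laplace ignores uncertainty in the learned scales; the
  MCMC backend quantifies it but is practical only for small designs.
- The exact Mann–Whitney enumerator is O(C(n+m, n)) and auto-switches to the
  normal approximation beyond n + m = 12.
- Fibre-typing thresholds are study-level knobs; defaults were fixed on
  synthetic data and should be inspected (e.g. via the unclassified fraction)
  before use on a new dataset.
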