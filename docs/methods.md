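# Methods

## Problem and model

Gene co-expression modules in single-cell data are usually called by
thresholding a gene–gene correlation matrix and clustering the resulting
graph. Two failure modes dominate at atlas scale:

1. **Compositional imbalance.** Common cell types dominate the covariance,
   so programs confined to rare states are under-recovered.
2. **Sparsity inflation.** Correlation estimates between sparsely expressed
   gene pairs are noisier (wider spread) than between dense pairs, so a
   fixed threshold admits excess false edges among sparse genes.

scdemon addresses the first with sample-side decorrelation (ZCA whitening)
and the second with an explicit sparsity calibration of the correlation
matrix.

### Decorrelation through the SVD

ZCA whitening transforms the data by `W = C^(-1/2)` so the transformed
covariance is the identity while staying maximally similar to the input.
Whitening the *cell* side of a cells × genes matrix `X` (n × g) equalizes
the weight of every cell-direction, removing the dominance of abundant
types. The n × n cell covariance is intractable at scale, but with the
truncated, **non-centred** SVD `X = U S Vᵀ` the covariance of the whitened
data reduces analytically to

    C_ZCA = g · V Sᵖ Vᵀ / n

with `p = 0` the fully whitened case and `p = 2` recovering the raw
non-centred covariance `g · XᵀX / n`. Because full whitening also removes
the large shared identity programs, the pipeline scans `p ∈ {0, 0.25, 0.5,
0.75, 1}` and combines the resulting graphs, so both rare and common
programs survive. No centring is applied anywhere: centring would break the
algebraic reduction, and the sparsity calibration below absorbs the
mean-driven offsets that centring would otherwise remove.

The covariance is rescaled to unit diagonal (symmetric rescaling with a
diagonal floor of 1e-12; entries clipped to [-1, 1]). Genes with ~zero
decorrelated variance cannot be rescaled and are flagged and excluded.

### Sparsity calibration

Every gene pair is binned by the two genes' sparsities (fraction of cells
expressing the gene, log10 scale; 20 equal-width bins per axis over the
observed range). Per bin, the mean and s.d. of the decorrelated
correlations are computed; both statistics are smoothed with weighted
least-squares bivariate splines (degree 3, interior knots at every other
bin center, weights `log(1 + bin count)`) and the correlation matrix is
z-scored against the smoothed surfaces:

    z_ij = (corr_ij − μ(s_i, s_j)) / max(σ(s_i, s_j), 1e-4)

Choices worth noting:

- **Knot placement instead of a global smoothing parameter.** A scattered
  smoothing spline caps its knot budget on a 20 × 20 grid and leaves
  systematic per-bin residuals (per-bin |mean z| up to ~0.17 on a null).
  Knots at every other bin center track the surface while the count
  weights still pool neighbouring bins; on an independent-gene null this
  keeps per-bin |mean z| below 0.1 and per-bin s.d. within (0.8, 1.2). If
  the knot set is infeasible for a sparsely populated grid, it coarsens
  stepwise and finally falls back to the scattered smoothing spline.
- The s.d. surface is smoothed on the raw scale; bins with fewer than two
  pairs are excluded from the s.d. fit.
- With fewer than 4 populated bins per axis (degenerate sparsity range)
  both surfaces fall back to global constants with a warning.
- The s.d. floor (1e-4) only guards near-empty bins against division
  blow-ups.

### Bootstrap over batches

Edges are stabilized by averaging z-matrices over 10 bootstraps, each
drawing `ceil(0.9 · B)` batches without replacement (the batch column is
the resampling unit — one sample, i.e. individual × region, in the
intended use). The SVD, correlation and calibration are recomputed per
bootstrap; the per-bootstrap SVD is shared across powers. Genes unexpressed
in a bootstrap's cells contribute nothing for that bootstrap and their
averages renormalize by the number of contributing bootstraps. The 5%
sparsity gene filter is applied once, on the full dataset, not per
bootstrap.

### Graphs and modules

The averaged z matrix is thresholded at `z > 4.5` into a gene graph per
power; connected components with fewer than 4 genes are removed; layouts
use Fruchterman–Reingold (seeded). The per-power graphs are combined by
multiplex Leiden clustering (RBConfiguration quality, equal layer weights,
resolution 3, seeded) over the union gene set; clustering uses the binary
adjacency (the thresholded graph), while edge z-weights are kept for
ranking. Modules with ≥ 10 genes are reported; smaller ones stay in the
assignment with a sub-threshold flag. "Core genes" (top half of each module
by summed within-module edge weight across layers, minimum 5, lexicographic
ties) are a pragmatic ranking — there is no canonical definition — and are
flagged as such.

A "published-data" preset pins `k = 100, z = 4.5, resolution = 2.5` for
cross-dataset runs.

### Choosing k

The SVD component count is grid-searched by stability: for each candidate
`k`, batches are split into two halves, the thresholded edge set is
computed on each half, and the Jaccard similarity between the two edge sets
is recorded; the most stable `k` wins. This criterion is this package's
construction (stability-based selection in the spirit of consensus
clustering); with fewer than two batches it falls back to `k = 100` capped
at `min(n, g) − 1`.

## Downstream statistics

- **Module scores**: mean normalized (CP10K + log1p) expression of member
  genes per cell. This is a deliberate, simple definition; a
  background-corrected variant (subtracting the all-gene mean per cell) is
  available behind a flag.
- **Covariate enrichment**: cells with score above mean + 1 s.d. (over all
  scored cells) are tested for enrichment in each covariate level with the
  upper-tail hypergeometric test; rows with p < 0.001 are flagged.
- **Module–module network**: scores aggregated per group (e.g. subtype ×
  sample), shifted to positivity and logged (`log(score − min + 1)`),
  Pearson-correlated per module pair with a one-sided (positive) test, BH
  adjusted, edges kept at adjusted p < 0.01. The positive one-sided
  direction reflects that the network connects co-expressed programs.
- **DEG-to-module enrichment**: each tested gene is assigned to the module
  whose average member-expression profile it correlates with most
  (zero-variance genes unassigned), then per module × category
  (up/down/ns) a hypergeometric test with BH correction is applied.
- **Contours**: per-cell values averaged on a 500 × 500 grid over the
  embedding bounding box and convolved with a normalized 25 × 25 Gaussian
  kernel (σ = 1); contour levels at 0.1–0.8 of the surface maximum.

## Synthetic data

The generator targets the statistical failure modes above, not any
particular tissue: negative-binomial counts (dispersion θ = 10, variance
μ + μ²/θ), log-normal library sizes (log-sd 0.3), per-batch × per-gene
multiplicative factors (log-sd 0.15), imbalanced cell-type proportions,
and a gene-sparsity gradient (baselines set from the NB zero-probability
inverse to target expressed fractions 0.02–0.95; module genes 0.10–0.90).
Modules are planted through per-cell latent activities (`a = type mean +
N(0, 1)`) entering the NB mean multiplicatively (`1 + λ·a`, floored at
0.01). The defaults (λ = 2, activity s.d. 1) realize a median within-module
Pearson correlation ≈ 0.5 on normalized data.

What the generator does **not** emulate: doublets, ambient RNA, cell-cycle
and other nuisance programs, UMI saturation, gene–gene correlation among
"background" genes, and realistic gene-length/GC effects. Passing tests
therefore demonstrate that the statistical machinery behaves as designed
under controlled conditions, not that any particular biological module set
is correct.

### Benchmark scenarios (problem sizes)

- **Planted recovery**: 5,000 cells × 2,000 genes, 5 modules × 60 genes, 3
  batches, 3 cell types (0.5/0.3/0.2), 10 bootstraps, powers 0–1, z = 4.5,
  resolution 3, seed 0 (versioned in `data/benchmark_scenario.yaml`).
- **Null calibration**: 500 cells × 2,000 independent genes spanning
  sparsities 0.05–0.95.
- **Imbalance stress**: 4,000 cells × 2,000 genes, types at 0.80/0.15/0.05,
  5 *exclusive* identity programs of 25 genes (activity varies only in the
  owning type), λ = 3, active mean 2. Module size matters structurally
  here: for an exclusive program the p = 0 decorrelated correlation of a
  within-module pair is bounded near `(1/m) / (1/m + k/g)` (signal share of
  a gene's V-row norm against the retained-noise share), independent of
  effect size once the program dominates its genes' variance. At g = 2,000
  and k = 100 a 60-gene exclusive module is therefore structurally capped
  near z ≈ 3 and unrecoverable at z = 4.5 for any effect size, while a
  25-gene module mirrors the atlas regime (module small relative to g/k)
  and is recoverable. The raw-covariance baseline (p = 2, uncalibrated,
  thresholded to the same edge count) misses the rare program entirely.

## Numerical and reproducibility notes

- Truncated randomized SVD (scikit-learn, 7 power iterations) with a
  deterministic sign convention (largest-|loading| V entry positive); all
  stochastic steps take explicit seeds, and the CLI writes a manifest
  (parameters, seeds, version, parameter hash) from which every output is
  reproducible byte-for-byte.
- Degenerate inputs: all-zero cells are dropped before normalization;
  never-expressed genes are dropped by the filter; empty graphs and empty
  module sets are valid outputs (with warnings), not errors.
- Module ids are assigned by decreasing size with lexicographic
  tie-breaking, so labels are stable across reruns.

## Known limitations

- The z-score normality assumption is parametric; no permutation null is
  provided.
- Whether module discovery should run on log-normalized or raw data is not
  settled; CP10K + log1p is the default and raw mode is a flag
  (`normalize_input: false`).
- The k grid-search criterion and the core-gene definition are this
  package's constructions (see above), documented as such.
- Layer weights in the multiplex clustering are equal; no attempt is made
  to weight powers by information content.
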