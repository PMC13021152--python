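# Methods

## Overview

`spatialsim` generates synthetic spatial single-cell molecular data — the kind
produced by multiplex immunofluorescence or imaging-based spatial
transcriptomics after cell segmentation and phenotyping — without requiring a
reference dataset, and uses it to benchmark univariate spatial summary
statistics. A simulated sample is built in fixed stages:

1. **Point pattern.** Cell locations are a homogeneous Poisson process of
   intensity λ (cells per unit area) on a rectangular window: the cell count
   is Poisson(λ·|W|) and locations are i.i.d. uniform. Before labelling, every
   sample is complete spatial randomness (CSR).
2. **Tissue compartments.** A probability surface assigns each cell to
   "Tissue 1" (high-probability regions) or "Tissue 2".
3. **Holes.** A second, independent surface flags cells lying in non-cellular
   regions (necrosis, tissue folds), for studying violations of stationarity.
   Flagged cells can be dropped at export or kept as a flag (default).
4. **Phenotype positivity.** One surface per cell type drives a Bernoulli
   positive/negative label per cell. With several cell types, type *t*'s
   surface is type *t−1*'s with every kernel centre translated — the `shift`
   parameter controls colocalization.
5. **Continuous markers (optional).** Positive cells draw marker values from
   Normal(μ₊, σ₊), negative cells from Normal(μ₋, σ₋), independently across
   cells and types.

## Probability surfaces

A surface is a set of k isotropic Gaussian bumps with centres uniform in the
window and bandwidths sd ~ Uniform(sdmin, sdmax). The raw field is the
pointwise **maximum** of the unit-peak bumps,

    s(x, y) = max_j exp(−((x−x_j)² + (y−y_j)²) / (2 sd_j²)) ∈ [0, 1],

mapped affinely onto the configured probability band:

    p(x, y) = prob_min + (prob_max − prob_min) · s(x, y).

Design choices made here, where the mechanism was genuinely open:

- **Max, not sum.** Combining bumps by max guarantees overlapping clusters
  never exceed `prob_max` and makes both band ends exact (the supremum
  `prob_max` is attained at every kernel centre; the floor `prob_min` is the
  far-field value). This is the one place a different simulator of the same
  design could diverge numerically; exact parity with any other
  implementation is not claimed.
- **Theoretical, not empirical, scaling.** The affine map uses the raw range
  [0, 1] rather than the empirical min/max over sampled points, so a surface
  is well defined independent of the point pattern it is applied to.
- **Kernel centres are uniform over the full window** (no margin inset), so
  clusters may straddle edges; the edge-corrected statistics must and do
  tolerate this.
- **Shift rule.** `shift ∈ [0, 1]` translates each centre by
  `shift · width/2` in an independent uniform direction with torus
  wrap-around. `shift=0` returns centres bit-identical (perfect surface
  sharing); `shift=1` displaces by half the domain — far beyond typical
  cluster bandwidths, destroying colocalization.
- Tissue assignment is stochastic (Bernoulli from the surface), not a hard
  threshold, mirroring the positivity mechanism; tissue, hole and phenotype
  surfaces are sampled independently of each other (no coupling such as
  phenotypes restricted to one compartment). Hole-flagged cells stay eligible
  for positivity; dropping them is an export-time decision.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window | (−1,1) × (−1,1) | spatial units | 2×2 domain centred at origin; a TMA-core-like field |
| λ | 250 | cells / unit area | ≈1000 cells per sample, a realistic segmented-core count |
| k (phenotype) | 5 | clusters | multiple clusters per sample |
| sdmin–sdmax | 0.1–0.3 | window units | tight clusters relative to the width-2 window |
| prob range (phenotype) | 0.01–0.75 | probability | low background positivity, high in-cluster abundance |
| tissue surface | k=2, sd 0.5–1.0, probs 0.2–0.8 | — | few broad compartments; chosen once, overridable |
| hole surface | k=1, sd 0.2–0.4, probs 0.1–0.3 | — | a single localized non-cellular gap; chosen once |
| distributions | none | — | no silent defaults: the ± separation is the condition under study and must be stated |

## Spatial summary statistics

All three estimators are recomputed here (no external spatial-statistics
package is called) and share one O(n²) pair-distance core used identically
for observed and permuted labels.

- **Ripley's K**, translation edge correction:
  K̂(r) = |W|/(n(n−1)) · Σ_{i≠j} 1{d_ij ≤ r} w_ij, with
  w_ij = |W| / ((W_x−|Δx_ij|)(W_y−|Δy_ij|)) ≥ 1. CSR reference πr².
- **Nearest-neighbour G**, reduced-sample (border) correction: among points
  farther than r from the boundary, the fraction whose nearest neighbour is
  within r. CSR reference 1 − exp(−λ̂πr²), λ̂ = n/|W|.
- **Pair correlation g**, Epanechnikov-kernel-smoothed pair-distance density
  with translation correction, normalized so CSR expectation is 1:
  ĝ(r) = Σ_{i≠j} κ_b(r−d_ij) w_ij · |W| / (2πr n(n−1)). Undefined at r = 0
  (reported missing). The "auto" bandwidth is Stoyan's rule 0.15/√λ̂,
  interpreted as the Epanechnikov kernel's standard deviation (support
  half-width √5 × that), following the convention of the standard spatial
  ecosystem. No reflection correction is applied at small r, so ĝ is biased
  low for r below the kernel half-width; the permutation test is unaffected
  because observed and null curves share the estimator.

The corrections (translation for K and g, border for G) are the standard
defaults of the spatial-statistics ecosystem; CSR closed-form tests pin them
down.

## Permutation "degree of clustering" test

For a sample with m positive cells among n, each of `n_perm` permutations
reassigns exactly m positive labels uniformly over all n cell locations —
the test is conditional on abundance — and recomputes the statistic. Per
radius:

- degree of clustering = observed − mean over permutations;
- one-sided p (toward clustering) = (1 + #{perm ≥ observed}) / (1 + n_perm),
  the add-one rule, never exactly 0;
- significance at level α means p < α (α = 0.05 by default; the threshold is
  a flag, since envelope-based rules are an equally defensible alternative).

Samples with fewer than two positive cells are non-evaluable and excluded
from per-radius significance denominators; the exclusion count is logged.
Radius r = 0 is excluded from assessment grids (g is undefined there), giving
the canonical 50-radius grid 0.01–0.5 by 0.01 on the default window.

## Benchmark scenarios and summary

Four scenarios cross cluster size with abundance (all at λ=250, k=5):
sd 0.1–0.3 vs 0.2–0.4, and probs 0.01–0.75 (high abundance) vs 0.01–0.2
(low). Per scenario the pipeline runs pattern → holes → tissue → positivity
(holes/tissue at module defaults; they are flags independent of the phenotype
surface and do not feed the statistics), then the permutation test for K, G
and g on every sample, with one shared set of permutations per sample serving
all three statistics.

Two headline counts per statistic over the 50 assessed radii:

- **most significant** — radii where the statistic flagged significant
  clustering in *strictly* the most samples; ties credit no statistic (so the
  three counts need not sum to 50);
- **all significant** — radii where 100% of evaluable samples were
  significant.

### Problem sizes

The package's benchmark runs default to a desk scale of 100 samples × 100
permutations per scenario (full-size runs are one flag away:
`--sims 1000`). The "most significant" comparison is stable under this
reduction. The "all significant" criterion is not scale-invariant: it becomes
strictly *easier* as the number of samples shrinks (a radius where each
sample is significant with probability q contributes with probability
q^(#samples)), so zero counts observed at large sample numbers can become
small positive counts at 100 samples when q ≈ 0.98 — this is a property of
the criterion, not of the estimators.

## Reproducibility

One master seed; every (stage, sample) pair derives an independent RNG
substream by counter (stage codes are fixed), so regenerating a later stage
never perturbs an earlier stage, samples are independent, and identical
config + seed reruns are byte-identical.

## What the generator does and does not emulate

The simulator reproduces the *geometry* of clustered, compartmentalized,
hole-pocked single-cell data and abundance-conditional marker positivity. It
does not model segmentation error, cell shapes or sizes (exported bounding
boxes are degenerate points), inhomogeneous background intensity,
count-distributed expression (markers are Gaussian only), anisotropic
clusters, or more than two tissue compartments. Passing benchmarks therefore
speak to a statistic's behaviour under idealized clustering/colocalization
geometry, not to robustness against those real-data artefacts.

## Numerical notes

- Pairwise distances are computed densely (n ≈ 1000 per sample → 10⁶ pairs,
  ~16 MB); permutation subsets index into the cached matrices.
- Translation weights are undefined for a pair spanning the full window
  extent in either axis (probability zero under the simulator); diagonal
  self-pairs carry d = +∞, w = 0 so they never contribute.
- With fewer than two points, estimator curves are all-NaN rather than an
  error; NaN permutation values (possible for border-corrected G at large r)
  are dropped from the p-value denominator.
- Windows are axis-aligned rectangles only; coordinates are continuous
  (no grid snapping).
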