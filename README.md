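# spatialsim

Simulate spatial single-cell molecular data — the per-cell tables produced by
multiplex immunofluorescence (mIF) or imaging-based spatial transcriptomics —
and benchmark spatial summary statistics against it.

Methods for quantifying cell clustering and colocalization in tissue lack an
agreed gold standard. `spatialsim` addresses this by generating biologically
realistic single-cell spatial data *without a reference dataset*: cells are a
homogeneous Poisson process on a rectangular window, and Gaussian-kernel
probability surfaces then assign tissue compartments, non-cellular holes,
phenotype positivity and continuous marker values. Because the generating
mechanism is known, the statistics' power and calibration can be measured
exactly.

The analysis side implements the three classical univariate summaries with
edge corrections, each against its complete-spatial-randomness (CSR)
reference:

- Ripley's **K(r)** (translation correction; CSR: πr²),
- nearest-neighbour **G(r)** (border correction; CSR: 1 − exp(−λπr²)),
- pair correlation **g(r)** (Epanechnikov smoothing, translation correction;
  CSR: 1),

and assesses clustering significance per radius by label permutation: the
statistic on the positive cells is compared with its distribution when the
same number of positive labels is scattered over all cell locations, giving
the *degree of clustering* (observed − permutation mean) and a one-sided
add-one p-value (1 + #{perm ≥ obs})/(1 + n_perm).

## Worked example

Simulate four samples at intensity 250 cells/unit area on a 2×2 window, with
five tight phenotype clusters and abundance scaled into [0.01, 0.75]:

```python
import numpy as np
from spatialsim import (Window, create_simulation_object,
                        generate_spatial_pattern, assign_holes, assign_tissue,
                        assign_cell_positivity, create_spatial_list,
                        summarise_spatial, permutation_test, default_radii)

obj = create_simulation_object(4, Window(-1, 1, -1, 1), seed=42)
generate_spatial_pattern(obj, 250)
assign_holes(obj)
assign_tissue(obj)
assign_cell_positivity(obj, k=5, sdmin=0.1, sdmax=0.3, prob_range=(0.01, 0.75))

tables = create_spatial_list(obj)
print(summarise_spatial(tables, "Cell 1 Assignment").to_string(index=False))
```

```
 Sample  Total Cells  Cell 1 Assignment Positive Cells  Cell 1 Assignment Percent Positive
      1         1029                               237                           23.032070
      2         1008                               255                           25.297619
      3         1001                               206                           20.579421
      4          999                               157                           15.715716
```

Each sample holds ≈ λ·|W| = 1000 cells, with 15–25% positive — inside the
configured [1%, 75%] abundance band, the exact fraction depending on how much
of the window the five sampled clusters cover. Now test the first sample for
significant clustering of the positive cells with Ripley's K:

```python
res = permutation_test(obj.patterns[0].xy,
                       obj.positivity[0][:, 0].astype(bool),
                       obj.window, default_radii(), stats=("K",),
                       n_perm=100, rng=1)
k = res["K"]
i = 9  # r = 0.10
print(f"r=0.10  K_obs={k.observed[i]:.4f}  CSR pi r^2={np.pi*0.01:.4f}  "
      f"null_mean={k.null_mean[i]:.4f}  degree={k.degree_of_clustering[i]:.4f}  "
      f"p={k.p_value[i]:.4f}")
```

```
r=0.10  K_obs=0.0601  CSR pi r^2=0.0314  null_mean=0.0305  degree=0.0297  p=0.0099
```

The observed K at r = 0.1 is about twice the CSR expectation (the permutation
null mean sits on πr², as it must), a degree of clustering of +0.03, and the
observed value beat all 100 permutations — p = 1/101 ≈ 0.0099, the smallest
value the add-one rule can produce.

Tables export as one CSV per sample, either verbatim or in a "halo-like"
dialect with degenerate XMin/XMax/YMin/YMax bounding-box columns for tools
that ingest digital-pathology exports.

## Command line

```sh
spatialsim run --config pipeline.yaml --out out/          # simulate + export
spatialsim export --input out/tables --out halo/ --dialect halo-like
spatialsim stats --input out/tables --marker "Cell 1 Assignment" \
    --stat K,G,g --radii 0.01:0.5:0.01 --perms 100 --out results.csv
spatialsim benchmark --scenario 1 --sims 100 --perms 100 --out bench/
```

`benchmark` runs one of four built-in scenarios crossing cluster size
(sd 0.1–0.3 vs 0.2–0.4) with abundance (probs 0.01–0.75 vs 0.01–0.2) and
tabulates, per statistic, the radii where it flagged significant clustering
in strictly the most samples and the radii where 100% of samples were
significant.

See `docs/methods.md` for the model, estimator formulas, default parameters
and their rationale, and known limitations.

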