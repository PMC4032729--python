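# leafmetric

Morphometry of eelgrass (*Zostera marina*) leaves from digital images.

Eelgrass blades are long, narrow ribbons — up to ~460 mm long but only
1.5–12 mm wide — and their area `a = l·h` (length times width) is the key
input to allometric, non-destructive estimates of leaf biomass and
productivity. Measuring `l` and `h` from a scan or photograph is attractive,
but the moisture film of a wet blade produces a *humidity halo*: a fringe of
pixels with colors intermediate between leaf and background that blurs the
peripheral contour. Because the blade is so narrow, even a one- or two-pixel
halo inflates the measured width, and with it the area, substantially.

`leafmetric` implements a segmentation-plus-selection procedure for this
problem:

1. **Segmentation by tolerance of similarity.** Pixels `P`, `Q` are similar
   at tolerance `ST(x) = [0, x]` when their RGB Euclidean distance satisfies
   `d_E(P, Q) ≤ x`, and connected when additionally 8-adjacent. Starting
   from a seed inside the blade, the leaf region is the connected component
   of the seed under this relation; its boundary pixels form the peripheral
   contour.
2. **Morphometry.** From the grown region: digital length `l_d = np_l/unp`
   and width `h_d = np_h/unp` (`unp` = pixels per mm; `np_l` the pixel
   extent along the blade's principal axis, `np_h` the pixel count on the
   cross-section at the midpoint of that extent), the proxy area
   `a_d = l_d·h_d`, and the Monte Carlo area `a_mc = LPN/UPN²` from sample
   points laid over the frame.
3. **Tolerance selection.** Each candidate `x` is scored against direct
   measurements on a cohort of leaves. Leaves are grouped by length into
   intervals `I_k = [q(k−1), qk)` (default `q` = 10 mm; groups with fewer
   than two leaves are excluded). With per-leaf errors `e = observed −
   image`, group means `δ^k`, cohort means `δ̄` and pooled standard
   deviations `σ_δ`, the proportion `λ_a` counts leaves whose group mean
   errors fall within `δ̄ ± σ_δ` for both length and width *and* whose area
   is not overestimated (`e_a ≥ 0`); `β_a = 1 − λ_a`. The selection index

       IS_x = β_a / λ_a

   (and `IS_x^mc` with the Monte Carlo area) is minimized over `x`: the
   optimal tolerance admits as much of the blade as possible while keeping
   the halo out.

The package also ships a synthetic-leaf generator that renders ribbon-like
blades with a parameterized humidity halo and known ground truth, so the
whole pipeline is testable without field imagery.

## Worked example

Generate a 50-leaf synthetic cohort with a 2-pixel humidity halo and sweep
seven tolerances across the leaf-to-halo color distance (≈ 73 here):

```python
import leafmetric as lm
from leafmetric.synth import CohortSpec, LeafSpec

cohort = CohortSpec(
    n_leaves=50, length_range=(20, 120), width_range=(2.5, 6),
    template=LeafSpec(true_length=100, true_width=4, unp=3,
                      halo_width=2, jitter=3),
)
samples = lm.generate_cohort(cohort, seed=42)
results = lm.ToleranceSweepModel(samples, [16, 40, 64, 90, 110, 160, 200]).fit()
print(results.summary())
```

```
Tolerance-of-similarity sweep
========================================================================
leaves: 50   groups (n_k >= 2): 10   partition: q=10 mm, n=12
     delta_bar_h  sigma_dh  delta_bar_l  sigma_dl  theta_l  theta_h  lambda_l  lambda_h  lambda_a  beta_a  is_x  lambda_amc  beta_amc  is_x_mc
x
16        0.0109    0.1002       0.0174    0.0804     0.18      0.0      0.82       1.0       0.4     0.6   1.5         0.4       0.6      1.5
40        0.0109    0.1002       0.0174    0.0804     0.18      0.0      0.82       1.0       0.4     0.6   1.5         0.4       0.6      1.5
64        0.0109    0.1002       0.0174    0.0804     0.18      0.0      0.82       1.0       0.4     0.6   1.5         0.4       0.6      1.5
90       -1.3224    0.1002      -1.3159    0.0804     0.18      0.0      0.82       1.0       0.0     1.0   inf         0.0       1.0      inf
110      -1.3224    0.1002      -1.3159    0.0804     0.18      0.0      0.82       1.0       0.0     1.0   inf         0.0       1.0      inf
160      -7.1735    0.0863      -6.6492    0.0804     0.18      0.0      0.82       1.0       0.0     1.0   inf         0.0       1.0      inf
200      -7.1735    0.0863      -6.6492    0.0804     0.18      0.0      0.82       1.0       0.0     1.0   inf         0.0       1.0      inf
------------------------------------------------------------------------
selected ST(x): x* = 16   IS = 1.5000   IS_mc = 1.5000
```

Reading the table: at tolerances below the leaf-to-halo distance (16–64)
the segmentation recovers the blade to pixel precision — mean width error
`δ̄_h` ≈ 0.01 mm — and area errors scatter around zero, so `λ_a` ≈ 0.4 and
the index is finite. At 90 and 110 the halo ring is annexed: the width is
overestimated by ≈ 1.3 mm (two 1/3-mm halo pixels per side), every leaf's
area is overestimated, `λ_a` drops to 0 and the tolerance is inadmissible
(`IS = inf`). At 160+ the region floods through the halo into the
background. The selection therefore lands on a halo-excluding tolerance,
`x* = 16`.

The command line mirrors this: `leafmetric synth` renders a cohort,
`leafmetric measure` prints one leaf's measurement row, and
`leafmetric sweep` writes the per-tolerance statistics CSV, an RMSD table
and a selection report JSON.

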