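# Methods

## The measurement problem

Eelgrass blade area is well approximated by length × width because the
blade is a near-rectangular ribbon. Both factors can be read off a digital
image once the blade's pixels are identified, but the identification is
ambiguous along the contour: a wet blade deposits a fringe of
intermediate-color pixels ("humidity halo") between leaf and background.
Since blade width is one to two orders of magnitude smaller than length, a
halo a few pixels wide biases the width — and hence the area — far more
than it biases the length. The package's job is (a) to segment a leaf at a
given color tolerance, (b) to measure it, and (c) to choose the tolerance
that keeps the halo out without fragmenting the blade.

## Segmentation

Colors live in the discrete RGB cube `[0, C_max − 1]³` (`C_max` = 256 by
default; images of other bit depths are rescaled on load and the rescaling
logged). Two pixels are *similar* at tolerance `ST(x) = [0, x]`,
`1 ≤ x ≤ C_max − 1`, when their Euclidean RGB distance is at most `x`; the
distance is kept in floating point and compared directly, with no rounding
before the comparison. Two pixels are *connected* when they are 8-adjacent
and similar. The leaf region grown from a seed is the connected component
of the seed in this graph.

Design choices:

- **Pairwise chaining.** Similarity is evaluated between adjacent pixels,
  not against the seed color. A chain of pairwise-similar pixels can
  therefore drift in color; this is intentional (it is how the halo gets
  annexed once `x` exceeds the leaf-to-halo distance) and the selection
  stage is the mitigation. No gradient-leak heuristic is added.
- **Borders.** The 8-neighborhood is clipped at the image frame; off-image
  space behaves as background. Border pixels simply have 3- or 5-element
  vicinities.
- **Implementation.** The component is extracted by thresholding a
  precomputed table of per-edge color distances and running a sparse-graph
  breadth-first search; the result is a pixel set, so traversal order never
  matters. The per-image edge table is computed once and re-thresholded for
  every tolerance in a sweep. Tests check equivalence against an
  independent pure-Python BFS over exhaustively enumerated edges.
- **Contour.** The peripheral contour is the set of members with at least
  one 8-neighbor (including off-image positions) outside the region,
  computed as the member mask minus its 8-connected erosion with the
  outside as border value. An ordered Moore boundary walk exists for
  visualization only.
- **Flood detection.** A region that reaches the image frame has leaked
  through the halo into the background; it is flagged per leaf and counted
  in the sweep diagnostics, never fatal.

## Morphometry

`l_d = np_l / unp`, `h_d = np_h / unp`, `a_d = l_d · h_d`, with `unp` the
image scale in pixels per mm.

- **Axes.** The length axis is the major principal axis of the member
  coordinates (largest-eigenvalue eigenvector of their covariance); for an
  axis-aligned blade this is the bounding-box axis. `np_l` is the pixel
  extent of the projection on that axis.
- **Width location.** `np_h` counts members in the unit-width slab
  perpendicular to the axis at the midpoint of the length extent, mirroring
  the manual protocol of measuring width halfway along the blade. A
  consequence worth noting: for a linearly tapered blade, length × midpoint
  width equals the trapezoid area exactly, so the proxy tracks the true
  area rather than over-covering it; a `width_mode="max"` flag measures the
  fullest cross-section instead, which does over-cover. Curvature
  correction of the length (arc-length measurement) is out of scope.
- **Monte Carlo area.** `a_mc = LPN / UPN²` with sample points over the
  whole frame; a point is inside the leaf iff the pixel containing it is a
  member (the region is inherently a pixel set, so sub-pixel membership is
  not defined). The default sampler is a deterministic grid of pitch
  `1/UPN` — reproducible with no seed bookkeeping; its error against the
  exact pixel-count area `|members|/unp²` is bounded by perimeter/UPN, and
  when `UPN` is an integer multiple of `unp` (the default is `UPN = 2·unp`)
  every pixel contains the same number of points and the grid estimate is
  exact. The alternative uniform-random sampler requires an explicit seed,
  which is recorded in the measurement row; its scatter follows the
  binomial standard error of point-in-region sampling.

## Grouped statistics and tolerance selection

Leaves are binned by observed length into intervals
`I_k = [q(k−1), qk)`, `q = l_max/n` (default `q` = 10 mm; the model rounds
`l_max` up to a multiple of `q`). The top interval is closed at `l_max` so
the longest leaf is not orphaned. Groups with fewer than two leaves carry
no dispersion information and are excluded; out-of-range leaves are
reported and logged, never silently dropped.

Per-leaf errors are observed minus image-derived (positive = the image
underestimates). For each tolerance:

- group mean errors `δ_l^k, δ_h^k, δ_a^k`;
- cohort means `δ̄_l, δ̄_h` over included groups;
- `σ_δl, σ_δh` as the **pooled within-group standard deviation** with
  denominator `Σ(n_k − 1)`. One cohort-level value per tolerance is needed;
  pooling uses every leaf and reduces to the ordinary sample SD when only
  one group exists. The choice is recorded in the output metadata.
- a group passes the length band iff `δ̄_l − σ_δl ≤ δ_l^k ≤ δ̄_l + σ_δl`
  (width analogously); proportions are leaf-weighted (a group's `n_k`
  leaves pass or fail with it);
- `λ_a` = fraction of leaves whose group passes both bands and whose own
  area error satisfies `e_a ≥ 0` (equality counts as consistent);
  `β_a` is the **full complement** (fails a band *or* overestimates), so
  `λ_a + β_a = 1` holds identically — the published worked-example rows sum
  to 1 up to print rounding, which this reading reproduces. The complements
  `θ` and `β` are counted directly rather than as `1 − λ`, so the identity
  is a genuine cross-check in the tests.
- `IS_x = β_a/λ_a`, `IS_x^mc = β_amc/λ_amc`. A tolerance with `λ_a = 0` has
  an undefined index and is reported inadmissible (`inf` in the sweep
  table). The selected `x*` minimizes `IS_x` over admissible rows; ties
  break toward the smaller `x`, which admits less noise.

Indices are stored at full precision; the summary display truncates (not
rounds) to four decimals, matching the convention of the reference tables,
and `stats_selection.truncate` exposes that convention for verification.

RMSD tables (observed vs. image-derived width, length, proxy area and
Monte Carlo area per tolerance) are produced for validation alongside the
index.

## Synthetic leaves

The generator renders what the field protocol photographs: one blade per
frame on a contrasting background.

- **Shape.** An axis-aligned ribbon, optionally linearly tapered and bowed
  by a half-sine midline; the default is the straight rectangle, for which
  the length-times-width truth is exact. The straight edge is anchored on a
  pixel boundary, so rasterized extents equal the physical extents rounded
  to the nearest pixel (error ≤ half a pixel per dimension).
- **Study conditions.** Lengths up to 460 mm and nominal widths within the
  species' reported 1.5–12 mm variation (default sampling band 2.5–6 mm,
  around the commonly observed maximum of 6 mm); specs outside these ranges
  are refused unless forced. Default scale `unp` = 5 px/mm; default leaf
  tone a mid green (40, 110, 60) on a near-white bed (235, 235, 240),
  leaf-background RGB distance ≈ 293.
- **Noise.** Intra-leaf jitter adds independent per-channel integer offsets
  (default ±3) inside the blade. The humidity halo is a ring of
  `halo_width` pixels (default 2) hugging the contour, with each halo
  pixel's color drawn from the straight segment between leaf and background
  color at a fractional position in `halo_span` (default 0.25–0.55). Placing
  halo colors strictly between the endpoint colors guarantees a threshold
  structure: tolerances below `0.25 × 293 ≈ 73` exclude the halo, tolerances
  above it annex halo pixels (inflating width), and tolerances beyond
  `0.45 × 293 ≈ 132` can leak into the background.
- **Determinism.** All randomness — cohort shapes, halo colors, jitter —
  flows from a single seed through named generators; the per-leaf seed is
  recorded in the manifest, and rendering is bit-identical for a fixed
  spec.

What the generator does *not* emulate: photographic texture, epiphytes and
attached sediment, specular highlights, lens distortion, curvature-induced
foreshortening, and multi-leaf scenes. Passing tests on these cohorts
demonstrate that the pipeline measures what the noise model describes — a
contour fringe of intermediate colors — not that it is robust to every
artifact of real field imagery.

## Problem sizes and numerical choices

The shipped tests and the acceptance script's self-check run desk-scale
cohorts: 50 leaves, lengths 20–150 mm, scales 3–5 px/mm, and sweeps of 5–7
tolerances — large enough that every length group in range is occupied and
the halo/no-halo regimes are both represented, while a full run stays in
seconds. The reference field cohort (809 leaves, 46 groups, full 1–255
sweep) is the same computation at larger n.

On noise-free cohorts with exact ground-truth observations, per-leaf area
errors are pure quantization (≤ half a pixel per dimension) with
near-symmetric sign, so `λ_a` hovers around 0.5 and the index around 1 at
every clean tolerance — selection among clean tolerances is then driven by
quantization coin flips, which is why the selection tests assert the
halo-exclusion property (the scientifically meaningful contrast) rather
than a unique clean `x*`. On halo cohorts, every leaf's area is
overestimated at halo-admitting tolerances, `λ_a` reaches exactly 0, and
those tolerances are inadmissible; an inadmissible index is treated as
worse than any admissible one, consistent with minimizing `IS_x`.

Degenerate inputs: a single-pixel region has `np_l = np_h = 1`; an
isotropic region takes the x axis as its principal axis; a cohort in which
no group reaches two leaves raises an explicit error ("no statistics
possible"); `λ_a = 0` raises in the index function and becomes `inf` in
the sweep table. Projection binning adds an epsilon (1e-9) before flooring
to keep exact integer projections in their intended slab, and the
4-decimal truncation adds the same epsilon to absorb binary representation
of exact decimal quotients.

## Known limitations

- Chained pairwise similarity can leak through smooth color gradients; the
  tolerance sweep exposes, but does not prevent, such leaks.
- The principal-axis length is a straight-line extent: strongly curved
  blades are under-measured (arc-length measurement is deliberately out of
  scope).
- The midpoint width is a single cross-section; local damage exactly at
  the midpoint shifts `np_h` (the max-width mode is a diagnostic
  alternative, not a default).
- Group acceptance bands use the pooled SD; with very few groups the band
  can be degenerate (all groups pass, or the band collapses when all
  errors are identical). Cohorts of a few dozen leaves or more avoid this
  in practice.
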