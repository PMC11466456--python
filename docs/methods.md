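# Methods

## Curvature index

A traced body midline is an ordered polyline in calibrated 2D coordinates
(y up; image input is flipped on load). It is resampled at `n_points`
positions spaced at equal arc-length steps `Δs = L/(n_points−1)` by linear
interpolation between trace vertices, endpoints preserved. At each interior
resampled point the local curvature is the signed Menger curvature — the
reciprocal of the circumradius of the circle through the point and its two
neighbours, `|κ| = 4·Area/(|a||b||c|)`, signed by the z-component of the
cross product of the entering and leaving chords (counterclockwise turns
positive). This estimator was chosen because it is parameter-free and exact
on circles: three cocircular points return exactly `1/R`, so the method has
zero bias on constant-curvature arcs at any sampling density.

Two summary statistics are reported per view:

- `raw_sum = Σ|κᵢ|` — the per-fish index used for group comparisons. It
  depends on `n_points` and on the coordinate unit (doubling the sampling
  roughly doubles it; scaling coordinates by `s` divides it by `s`), so it is
  only comparable within one configuration; every result therefore records
  `n_points` and the unit, and `combined_curvature_index` refuses to sum
  views computed under different configurations.
- `arc_integral = raw_sum·Δs` — the discretisation of the total absolute
  turning `∫|κ|ds` in radians. It is invariant under rigid motions and
  uniform scaling, and converges to `2π` on a simple closed convex curve;
  it is the recommended quantity when configurations differ.

The per-fish index sums the lateral and dorsal views.

**Endpoints and closure.** Curvature is undefined at the two trace
endpoints; open traces yield `n_points − 2` values with no padding. A closed
trace (first and last point coincident, auto-detected) instead wraps around
the seam and yields one value per distinct point — without this the missing
seam sample biases the total turning of a closed polygon by `2π/(n−1)`,
which at 721 points is an 0.9% error; with it the 721-point circle
reproduces `2π` to better than `1e−6`.

**Defaults.** `n_points = 50`. This matches the scale of manual traces
(tens of anchor points over a fish silhouette) and keeps the raw index
stable between repeated traces; it is configurable everywhere and recorded
in every output.

**Smoothing.** An optional moving-average pre-filter over the resampled
points (`smooth_window`, odd, default 1 = off) suppresses high-frequency
jitter. It matters for midlines extracted from rasterised masks, where the
skeleton wobbles by ±half a pixel: on a 400-px fish at `n_points = 50`,
`smooth_window = 5` reduces the round-trip index error from ~10% to ~4%
(see the mask round-trip below). It should be left off for clean analytic
or carefully traced inputs.

**Sign convention.** Counterclockwise positive in a y-up frame. Only |κ|
enters the index, so the sign affects diagnostics (e.g. inflection
counting), not results.

## Cobb angle

Each spinal curve is measured from two landmark lines drawn parallel to the
most displaced vertebrae (a manual choice; an automatic selector is out of
scope). The angle is the acute angle between the undirected lines,
`acos(|d̂₁·d̂₂|)` in degrees ∈ [0, 90]. The clinical construction measures
the angle between perpendiculars to the two lines; both formulations are
implemented with identically ordered arithmetic so they agree exactly (not
just to rounding), and the equality is asserted over random line pairs in
the tests. The total Cobb angle of a fish is the plain sum over all curves
and both views; an empty list gives 0.

## Embryo deflection angle and rose plots

With `u = yolk − eye` and `v = tail − yolk`, the deflection is the direction
of `v` in a frame where `u` points along 0° and counterclockwise is
positive, mapped to [0, 360). This measures deflection *relative to the
head axis* rather than the absolute image-frame direction of `v`; with
standardised head-left imaging the two coincide up to mounting variation,
and the relative reading is the one that is invariant to imaging rotation,
which is why it is the default. Angles are binned into left-closed 30°
sectors `[30k, 30(k+1))`; out-of-range inputs are normalised modulo 360
with a warning, and bin counts always sum to the number of inputs.

## Midline extraction from masks

Binary silhouettes are reduced to a midline by: largest 8-connected
component → morphological skeleton (scikit-image) → longest geodesic path
between skeleton endpoints on the 8-connected pixel graph (edge weights 1
and √2, two-sweep Dijkstra as for a tree diameter) → orientation by a head
hint (or leftmost endpoint) → optional truncation at a configurable
fraction of path length (default 1.0), for stopping at the tail base when
the fin is included in the mask. Taking the single longest path prunes fin
side-branches, matching the single mouth-to-tail line a human tracer draws.
Extraction is deterministic; ring-shaped masks (no skeleton endpoints) are
an error, and masks without an elongated axis (a disk) produce a warning.

## Penetrance kinetics

At week *t* the numerator is the number of fish with recorded onset ≤ *t*;
the denominator adds the fish still straight and under observation at *t*.
Never-curved fish that left observation earlier (deaths, removals) are
censored from later denominators; fish with a recorded onset remain counted
permanently because scoliosis does not revert. This keeps every curve
non-decreasing and within [0, 100] for any input — a per-timepoint
denominator that also dropped curved fish after their last observation
could dip. Variance estimation and survival-model machinery are out of
scope; the module emits tidy tables for standard statistical routines.

## Comparative-Ct quantification

Replicate Ct values are averaged arithmetically per (sample, gene) —
instruments report duplicates and the arithmetic mean of cycles corresponds
to the geometric mean of quantities, the standard aggregation. Then
`ΔCt = C̄t(target) − C̄t(reference)` per sample; with a control group,
`ΔΔCt = ΔCt − mean ΔCt(control)` and fold `= 2^−ΔΔCt`, otherwise
`2^−ΔCt`. Identities that follow and are asserted: ΔΔCt = 0 ⇒ fold 1;
using the whole dataset as its own control makes the geometric-mean fold
exactly 1; shifting all reference Cts by `c` multiplies every `2^−ΔCt` fold
by `2^−c`. Amplification-efficiency correction is out of scope.

## Omics filtering and overlap

The deregulation criterion is strict: `p < 0.05` **and** `log2FC > 0.75`
(up) or `< −0.75` (down); boundary rows are excluded, matching the
"< 0.05" / "> 0.75" convention. Rows whose selected p column is missing
(adjusted-p NA from DESeq2's independent filtering) are excluded from both
sets — the conservative reading — with `p_column="pvalue"` as the explicit
fallback. Processed proteome tables use the same schema and code path; for
a proteome the choice of raw vs adjusted p is genuinely ambiguous in
practice, so both are supported and the synthetic proteome generator plants
rows that pass under either column, making the reproduction insensitive to
the choice. Identifier handling trims whitespace and is case-sensitive by
default (zebrafish gene symbols are case-meaningful), with a
case-insensitive switch. Overlaps and target cross-references are exact set
algebra after normalisation. Volcano export writes `x = log2FC`,
`y = −log10 p` and a class column consistent with the filter; zero p-values
are clamped to the smallest positive float with a warning.

## Synthetic data

Each generator is a pure function of its parameters plus one explicit seed
(no global random state), and its output carries the planted truth so the
downstream estimator can be checked exactly or within a stated analytic
tolerance:

- **Midlines** — straight lines, circular arcs (truth: sweep angle), sine
  curves and "scoliotic" shapes (1–3 superposed sine modes with random
  phases; one amplitude knob controls severity, giving the monotonicity
  tests a single axis). Truth for the total turning is computed by adaptive
  quadrature of `|y″|/(1+y′²)` before jitter is added.
- **Masks** — tube of given half-width around a midline via distance
  transform. The `≤`-threshold rasterisation widens the tube by one pixel,
  so area checks against `2wL` should use half-widths ≳ 8 px.
- **Vertebral lines** — a random base line plus a copy rotated by the true
  angle and translated, so the measured Cobb angles equal the planted ones
  to machine precision.
- **Embryo cohorts** — von Mises-distributed deflection angles (or a
  verbatim list), with the generator's own rose-bin bookkeeping as truth.
- **Feature tables** — planted up/down features pass the strict criterion
  by construction, nulls fail at least one threshold by construction, and a
  tenth of the nulls get NA adjusted p to emulate independent filtering.
  Default sizes emulate the modelled study: trunk 614 up / 75 down and
  brain 60 up / 1 down among 20 000 genes with 54 shared upregulated genes,
  a target list hitting 106 (77 direct) of the trunk up-set, and a
  5706-protein proteome with 127 up / 45 down.
- **Onset cohorts** — binomial curvature at the stated penetrance (default
  0.9, n = 252) with onsets uniform in a 4–11 wpf window, observation to
  16 wpf.
- **Ct tables** — the planted fold shifts the mutant target Ct by
  `−log2(fold)` cycles (default 3.5-fold, 7 mutant vs 5 control fish,
  duplicate measurements, 0.1-cycle technical noise; per-fish biological
  scatter available but off by default).

What the generators do **not** emulate: photographic segmentation noise,
anatomically realistic fish silhouettes (fins, pigment gaps), qPCR
efficiency differences, correlated expression structure or realistic
p-value/log2FC joint distributions in the null features. Passing tests
therefore demonstrate correctness of the computations and estimators on
known geometry and planted effects — not robustness to the full messiness
of real images or sequencing data.

## Numerical choices

- Near-duplicate consecutive trace points (closer than `1e−9·L`) are merged
  on load with a warning; fully degenerate traces are errors.
- `resample_equidistant` pins the first and last resampled points to the
  source endpoints to avoid floating-point drift at `s = L`.
- `cobb_angle` clamps the cosine to 1 before `acos`, so parallel lines give
  0 within ~1e−5 degrees rather than NaN.
- Deterministic problem sizes throughout the test-suite and the acceptance
  script: 20 000-gene tables, 252-fish cohorts, 200-point sine recovery,
  400-px mask round trips — sizes at which every stage's tolerance is met
  with margin and the whole suite runs in seconds.

## Known limitations

- The raw curvature index is sampling- and unit-dependent by construction;
  cross-study comparison requires either identical configuration or the
  arc-integral mode.
- The skeleton-based extractor assumes an elongated, roughly tube-like
  silhouette; it will silently straighten a self-overlapping (U-turned)
  fish, and retracts from the true snout/tail tips by about the local
  half-width.
- Rose binning at 30° conceals within-sector structure; the deflection
  angles themselves are always exported alongside the histogram.
- Penetrance curves carry no confidence intervals; export the tidy table to
  a survival package if uncertainty is needed.
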