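# Methods

This note documents the models, conventions and numerical choices behind
rhizobridge, and what the synthetic test conditions do and do not show
about real data.

## Thermal time and rooting phenology

Daily mean temperature T (°C) is converted to unitless increments:

- **Chilling units**: a triangular piecewise response, zero at or below
  −3.4 °C and above 10.4 °C, 0.159·T + 0.506 on (−3.4, 3.5] and
  −0.159·T + 1.621 on (3.5, 10.4]. The two line segments do not meet the
  zero branch exactly at the window edges, so CU is slightly negative just
  above −3.4 °C (−0.0346 in the limit). We implement the printed segments
  exactly and do not clamp; cumulative sums over realistic seasons are
  unaffected beyond the third decimal.
- **Forcing units**: FU(T) = 1/(1 + e^(−0.47·T + 6.49)), a logistic bounded
  in (0, 1) with midpoint 6.49/0.47 ≈ 13.81 °C. The coefficients follow the
  published forcing function for temperate-conifer heat accumulation.
- **Growing degree days**: max((T_max + T_min)/2, 0) with no upper cap.

Cumulative series are plain running sums from a stated start date. Missing
calendar days are a hard error rather than being interpolated: a silent
gap would corrupt every downstream cumulative value.

**T50.** Within a cohort of n cuttings tracked daily, the cumulative
fraction rooted by day d is fit with the two-parameter log-logistic
F(t) = 1/(1 + exp(b·(ln t − ln e))), the standard two-parameter dose- and
time-response form; T50 = e. Two numerical choices matter:

- *Interval correction.* A recorded rooting day d stands for continuous
  emergence times rounded to day d, so the fraction rooted "by day d" is
  the CDF at d + ½, and the fit evaluates there. Without this the estimate
  is biased half a day early — large relative to its standard error at
  realistic cohort sizes.
- *Standard error.* The least-squares covariance from the curve fit is
  anti-conservative because cumulative fractions on successive days share
  cuttings. We instead report the delta-method variance of the fitted
  median: Var(T50) = [F(1−F)/n] / f(T50)² with F = ½ and density
  f(T50) = |b|/(4·T50). Under the simulated study condition (n = 200,
  true T50 = 12 d, shape 8) the estimator is unbiased to <0.1% and the
  nominal 95% interval covers the truth ≈96% of the time (measured over
  200 replicates in the test suite).

Cohorts in which fewer than half the cuttings ever root have no
identifiable median and raise; optimizer failure is reported through a
``converged`` flag, not an exception. T50 is regressed on cumulative
thermal time by ordinary least squares; MSE is the mean squared residual
(n denominator), and significance is the two-sided slope t-test.

## Trait extraction

Inputs are binary masks (nonzero = root) with an explicit mm-per-pixel
scale; segmentation of raw photographs is upstream of this package.
Conventions:

- 8-connectivity for foreground, 4-connectivity for background holes (the
  standard dual pairing; anything else produces paradoxical hole counts).
- Components smaller than 2 pixels are removed before measurement
  ("smaller than" strict, so 2-pixel components survive); the filter is
  idempotent.
- The skeleton is the standard topological thinning; tips are skeleton
  pixels of degree ≤ 1, branch points degree ≥ 3. "Number of roots" is
  operationalized as the tip count, the usual convention for whole-root
  images where axis identity is not tracked.
- **Length.** Summing raw 8-connected steps (1 or √2 px) overestimates
  straight runs by up to ~8% depending on angle. We therefore decompose
  the skeleton into chains between tips/junctions and sum chord lengths
  over 4-pixel windows — exact for straight runs, and following curvature
  closely. Residual error on constructed straight-line fixtures is below
  1%; the documented tolerance is 5% to leave room for junction geometry
  in branched systems.
- **Diameter.** diameter = (2·EDT − 1)·scale at skeleton pixels, where EDT
  is the Euclidean distance transform in pixels. Exact for odd pixel
  widths, within one pixel for even; the documented tolerance is 1 px.
- **Convex area** is the pixel count of the rasterized convex hull
  (scikit-image) × scale², not the polygon area of pixel centers: the
  rasterized hull contains every foreground pixel, so solidity =
  network/convex is guaranteed ≤ 1 even for one-pixel-wide shapes.
- **Orientation** is the length-weighted mean absolute angle of skeleton
  steps from the downward vertical, in [0°, 90°]; digitization tolerance
  2°.
- Surface area models each skeleton step as a cylinder at the local
  diameter. An empty mask yields an all-zero record with solidity NaN.

## Trait → parameter equations

The per-order growth-model parameters are derived from {min, median, max}
summaries of the trait table plus the elapsed observation time t (days).
The equations live in a declarative table (one lambda per parameter) so a
single line changes a grouping. Operands are converted mm → cm before
application; the adopted equations are:

| parameter | equation (cm units) |
|---|---|
| l_b | (RootLength_min / NumberRoot_min) · (1/RootOrder) |
| l_a | ((RootLength_max − RootLength_median) / NumberRoot_max) · (1/RootOrder) |
| l_n | (SurfaceArea_median[cm²] / NumberRoot_median) · 5/RootOrder² |
| l_max | Depth_max · 1.2 / RootOrder³ |
| r | ((RootLength_max − RootLength_min)/t) · 1.5/RootOrder |
| Δx | 0.5 (primary), 0.1 (secondary, tertiary) |
| σ | sample SD (ddof = 1) of per-record mean orientation |
| θ | median per-record mean orientation |
| N | RootOrder |
| a_i | (Diameter_min / NumberRoot_min) / RootOrder² |
| a_max | Diameter_max / (5·RootOrder²) |
| a_r | (a_max − a_i)/t, converted cm·d⁻¹ → mm·h⁻¹ |

Design notes:

- The source for several constants is typographically ambiguous; the
  adopted readings (1.2, 1.5, the area division absorbed into the mm²→cm²
  conversion) are the ones that keep every derived parameter in a
  biologically plausible range for fine adventitious roots (l_max tens of
  cm, r ~1–2 cm/d, lateral spacing ~1–8 cm) and make the
  parameterize→simulate→re-extract loop approximately self-consistent.
  The alternatives (literal 12, 15, and spacing of ~0.05 cm) imply
  meter-scale axes and tens of thousands of laterals per parent.
- l_b is the unbranched zone at the *base* of an axis and l_a the
  unbranched zone behind the *tip*, the geometric roles these symbols play
  in the growth model; labels in derived literature vary, so the
  simulator's code names the zones by position, not by symbol.
- σ is kept in the degrees-based orientation scale under the model's cm⁻¹
  label; see the tropism section for how it becomes an angle.
- a_r is derived after a_i and a_max; a sample in which a_i ≥ a_max yields
  a slightly negative a_r, which the realization floors at zero and the
  validator flags as a diagnostic rather than an error.
- These equations are length-homogeneous of degree 1 in the length traits
  (and degree 2 for the area-derived l_n) — scaling inputs by c scales the
  derived lengths by c (c² for l_n) — verified by property test.
- Parameter recovery is contract-tested: simulating with known (r, l_max),
  rendering, extracting and re-deriving tracks the truth with Spearman
  ρ > 0.7 over 20 parameter sets, with rates identified from an
  active-growth imaging window (days 3–9) and maximal lengths from mature
  systems (days 45–50). The two windows matter: once growth saturates at
  l_max, the observable length range no longer carries rate information,
  and before saturation the maximal length is not yet expressed. This is
  a property of the equations, not of the implementation.

## Growth model

Internal geometry is in mm, depth positive down; parameters arrive in the
cm-based units above and are converted at the boundary. Each axis draws
its parameters once at birth from truncated normal distributions: the
supplied value is the mean, the spread is sd = 10% of the mean truncated
to [max(0, mean − 2sd), mean + 2sd] (configurable; the source model family
is explicitly stochastic but does not publish per-parameter spreads), and
the insertion angle θ uses the measured orientation SD σ as its spread.
Draws happen in a fixed order from a per-axis generator spawned from
(seed, axis id), so identical configurations are bit-reproducible and the
creation of one axis never perturbs another's draws.

- **Elongation**: l(age) = l_max·(1 − e^(−r·age/l_max)); initial slope r,
  asymptote l_max, never surpassed (growth saturates rather than halts).
  The functional form is the negative-exponential of the CRootBox lineage;
  it is isolated in one function so a linear-then-stop variant can be
  swapped in.
- **Sub-segments and tropism**: each step extends an axis to its target
  length in sub-segments of arc length ≤ Δx. Before each sub-segment, N
  candidate headings are drawn — rotate the current heading by a polar
  angle ~ N(0, σΔx) about a uniform azimuth — and the candidate minimizing
  the tropism objective is kept: angle to downward vertical
  (gravitropism), |angle to the horizontal plane| (plagiotropism), or
  angle to the axis's initial heading (exotropism). N = 1 is a pure random
  walk; N = RootOrder (the table's value) gives weak steering for
  primaries, which is implemented as specified. σΔx = Δx·σ with Δx in cm;
  because σ descends from an orientation spread in degrees, the product is
  interpreted as degrees and converted to radians for the draw.
- **Branching**: branch sites occupy [l_b, l_max − l_a] at spacing l_n
  (fencepost count ⌊zone/l_n⌋ + 1, realized per axis); a spacing longer
  than the whole axis disables branching. A lateral initiates on the step
  after its site is overtaken by the parent tip, with polar insertion
  angle drawn around θ and a uniform radial angle; there is no additional
  emergence delay parameter.
- **Radii**: a node's radius grows from a_i toward a_max at a_r
  (mm·h⁻¹ → mm·d⁻¹ internally) with the node's age, so basal nodes are
  thicker than the tip.
- **Confinement**: points leaving the slab or cylinder are mirror-reflected
  across the violated boundary and the heading component normal to that
  boundary is negated; reflection iterates for corner cases. The slab's
  thin out-of-plane dimension is deliberately allowed to be smaller than a
  growth step — repeated reflection is what keeps quasi-2D pouch growth
  planar (max out-of-plane coordinate ≤ thickness/2 by construction).
  In-plane extents must exceed twice the largest Δx, checked at start-up.
- **Rendering**: orthographic projection onto the xz or yz plane, each
  segment stroked at its local diameter with round caps; world coordinates
  map to pixel centers (half-pixel offset) so thin strokes do not jitter
  across pixel boundaries. An optional trim radius removes segments whose
  endpoints lie farther than that 3D distance from the stem base,
  mirroring the trimming of excavated crowns before imaging.
- **Serialization**: RSML 1.0 (scene → plant → nested roots, polyline
  geometry in mm, per-point diameter function, root order annotation) and
  a flat per-segment CSV, both round-trip to 1e−6 mm; identical config +
  seed yields a bit-identical CSV.

All primaries start at the stem base heading straight down. Whether the
60° incline of a pouch rack should tilt the gravity vector in quasi-2D
simulations is not settled; the default keeps gravity vertical.

## Evaluation

Samples are whole plants/images, never individual roots (pseudo-replication
guard). k-fold cross-validation (default k = 5) partitions samples into
near-equal folds; all C(5,3) = 10 permutations of 3 training / 2 test
folds are evaluated, and an iteration count (default 10) re-draws the
split. Training folds parameterize the model; one simulation is produced
per test sample; each shared numeric trait is compared observed-vs-
simulated by a two-sided Welch t-test (pooled-variance variant available
by flag; the unequal-variance form is the safer default when simulation
variance differs from biological variance). Bonferroni adjustment is
applied over the trait family of one comparison, never across iterations.
An adjusted p < α (default 0.05) is a misclassification; the sensitivity
rate is 100·(n − misclassified)/n. Pipeline failures flag the permutation
in the summary rather than silently dropping it. Under a same-distribution
null with 20 traits the family-wise misclassification rate is ≈0.04,
within Monte-Carlo noise of the nominal 0.05 (1,000 replicates).

## Synthetic data

The generators produce every input the pipeline needs, each with
machine-readable ground truth carried alongside so tests never re-derive
truth from an image:

- **Weather**: sinusoidal season + Gaussian noise; the max/min bracket
  scales with the noise so a noiseless series is exactly constant.
- **Cohorts**: rooting days from a log-logistic with known median and
  shape, rounded to whole days, censored beyond the observation window.
  Default study condition: n = 200 cuttings, T50 = 12 d, shape 8 — a
  cohort size at which the T50 machinery can be meaningfully calibrated.
- **Masks**: analytic polylines stroked at known widths (default scale
  0.1 mm/px for standalone fixtures; the test fixtures use 0.5 mm/px to
  keep images small). Truth: exact summed length, tip count,
  length-weighted orientation, width statistics.
- **Round trips**: simulate → render → extract, packaged with the
  simulator's own geometry as oracle.

What the synthetic conditions do **not** show: real segmented images
carry noise the generators omit — segmentation holes and speckle beyond
the 2-px filter, root overlap and crossing in dense mats, illumination
artifacts, and the hydroponic-transfer distortion of insertion angles.
Passing the recovery tests demonstrates that the measurement and
simulation machinery is internally consistent at the stated tolerances;
it does not certify trait accuracy on noisy field imagery. Likewise the
2D projection of a 3D simulation merges overlapping axes, so re-extracted
length underestimates analytic length by ~20–30% in dense systems — the
same occlusion an observed photograph suffers, which is why evaluation
always compares like with like (both sides re-extracted through the same
pipeline).

## Problem sizes

The shipped test suite and acceptance script run everything at desk
scale, chosen as the smallest sizes at which each statistical claim is
testable: 12 observed plants for the cross-validated pipeline (the
minimum that leaves ≥ 2 samples per group in every fold permutation),
200-cutting cohorts for T50, 1,000 replicates for the family-wise error
measurement, 20 parameter sets / 20 seeded fixtures for the recovery
contracts, and 21-day two-order simulations in the standard pouch
domain.
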