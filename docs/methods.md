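# Methods

## Model

An image with nonnegative pixel intensities `A(x, y)` is reduced, at
each analysis scale `eps` (box side, in pixels), to the probability
vector of its box measures: the image is tiled by `eps x eps` squares
anchored at the top-left corner, and box `i` receives

    mu_i = (sum of A over box i) / (sum of A over the image),

so `sum_i mu_i = 1` at every scale.  The order-`alpha` Rényi entropy of
this vector, in nats,

    H_alpha(eps) = 1/(1 - alpha) * log( sum_{mu_i > 0} mu_i^alpha ),

interpolates the classical cases: `H_0` is the log of the number of
occupied boxes, `H_1` the Shannon entropy `-sum mu log mu`, `H_2` the
collision (correlation) entropy.  Terms with `mu_i = 0` are excluded
from every sum; `H_1` is always computed by its closed form, never as a
numeric limit.  The scale-dependent generalized dimension is the
negative derivative of entropy with respect to log scale,

    D_alpha(eps) = - dH_alpha / d log(eps),

estimated by LOWESS: at each observed `x0 = log(eps)` a quadratic is
fitted to `(log eps, H_alpha)` by weighted least squares with Gaussian
weights `w(x) = exp(-((x - x0)/sigma)^2)`, and `-p'(x0)` is the
dimension estimate.  No limiting dimension is assumed to exist; the
curve `D_alpha(eps)` itself is the result, and any single-number
summary is an explicit band mean over a stated scale interval.

Assumptions worth keeping in mind: intensities must be nonnegative
(measures are intensity fractions); the tiling is anchored, not
sliding, so estimates carry a grid-phase component that the LOWESS
bandwidth smooths; and entropies are in natural log units throughout
(a bits conversion is available in the tidy output only).

## Computation

The box sums at all scales come from one summed-area table
`B[x, y] = sum_{a<=x, b<=y} A[a, b]` with a virtual zero row/column;
the sum over any rectangle `x1 < a <= x2, y1 < b <= y2` is
`B[x2,y2] - B[x1,y2] - B[x2,y1] + B[x1,y1]`.  Accumulation is in
float64, and the property suite enforces `|block - bruteforce| <=
1e-9 * total`.  Coarse-graining at every `eps` in `1..E` then touches
on the order of `sum_eps area/eps^2 <= (pi^2/6) * area` cells — an
operation-count contract asserted in the tests (with a 10% allowance
for ceil inflation of ragged edge tiles), not a wall-clock claim.

**Ragged edges.**  When `eps` does not divide the image side, the
partial edge tiles are kept as boxes of their own.  This keeps
`sum mu_i = 1` exactly at every scale, which the entropy definitions
need; the alternatives (cropping, zero-padding) either discard measure
or inject spurious empty boxes.  The cost is a known artifact at very
large scales: with `m = side/eps` boxes per side, a fully occupied
image counts `ceil(m)^2` boxes, so the measurable log–log slope of a
plane-filling pattern is capped near `2m/(m + 0.5)` — about 1.9 at
`m = 10` but under 1.5 at `m = 3`.  Analyses here therefore report
dimension summaries only for `eps <= side/8`, and the entropy grid is
extended past the reporting band so the band's LOWESS fits are
two-sided (one-sided boundary fits are flagged `edge` in the output).

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `sigma` | 0.5 | LOWESS bandwidth, in natural-log-scale units; 0.3 resolves local structure (and its oscillations), 1.0 smooths toward the global slope |
| `degree` | 2 | local polynomial; quadratic captures curvature of `H(log eps)` without the boundary bias of a linear fit |
| `alphas` | 0, 1, 2 | the three orders with direct physical readings; arbitrary nonnegative orders accepted, negative orders refused unless forced (empty boxes make `sum mu^alpha` explode under noise) |
| scale grid | all integers `2..side/4`, or ~40 log-spaced integers above 512 px | the derivative is taken in `log eps`, so log spacing loses nothing on large images |
| `pixel_size` | none | µm per pixel; required for physical-band operations (threshold optimisation, band means in µm) |

## Fixture generators

Each generator attaches the exact Hausdorff dimension of the set it
renders, so validation harnesses consume only that metadata.  Curves
are rasterised as 1-px binary strokes without anti-aliasing (gray
strokes would perturb the `alpha > 0` entropies).  Validation problem
sizes: snowflake 4096 px / 6 refinements (min segment ~4.9 px), Pascal
mod 3 at 2187 px, carpet 3^7 = 2187 px, island 2048 px / 4 refinements
(min segment ~4.8 px), chaos game 2000 px, Brownian surfaces 1025 px.

* **Koch snowflake** (log4/log3 ≈ 1.262): triadic refinement of an
  equilateral triangle; 3·4^k segments.
* **Quadric Koch island** (3/2): square initiator, each edge replaced
  by 8 quarter-length segments; 4·8^k segments.  Below its shortest
  rendered segment the curve is genuinely linear, so `D_0` breaks from
  ~1 toward 3/2 around that scale — the fixture for scale-break
  behaviour.  Like all exactly self-similar renderings it has discrete
  characteristic scales (multiples of 4 times the minimum segment) at
  which the estimate dips; with ~4.8 px segments the 20–50 px band mean
  reads ≈ 1.46 rather than 1.50.
* **Sierpinski carpet** (log8/log3 ≈ 1.893): exact digit construction;
  8^k filled pixels.
* **Pascal's triangle mod 3** (log6/log3 ≈ 1.631): Lucas' theorem,
  digit-wise comparison in base 3; characteristic triangle sizes 3, 9,
  27, … px produce the documented periodic dips in `D_0(eps)`.
* **Chaos-game Sierpinski triangle** (log3/log2 ≈ 1.585): midpoint
  iteration toward random vertices, 10-step burn-in, each iterate one
  pixel.  Sparse renderings are point-like at small scales and reach
  the ideal scaling only at large scales; the estimate at a fixed scale
  grows monotonically with the point count.
* **Fractional Brownian surfaces** (surface dimension `D = 3 - H`):
  drawn *exactly* by circulant embedding of Stein's compactly
  supported stationary covariance `c(r) = c0 + c2 r^2 - r^(2H)`
  (`r <= 1`; a matched cubic tail out to `r = 2` when `2H > 1.5`).
  Plain spectral power-law filtering was rejected after its increment
  variance measurably violated the `lag^(2H)` law at low Hurst
  (fitted exponent 0.63 instead of 0.40 at `H = 0.2`); the embedded
  kernel field keeps the fitted exponent within 0.03 of `2H` across
  `H` in 0.1–0.9, except `H = 0.9` where the analytic `c2 r^2` term
  leaves a ~0.08 shortfall at 32-px lags.  The *drift-corrected* exact
  fractional Brownian field was deliberately not used: its large-scale
  trend concentrates the median level set into a few contour loops
  (which measure the loop dimension `1.5 - H/2`), whereas the
  stationary field's level set is the full `2 - H`-dimensional set the
  outline fixtures are meant to realise.
* **Surface outlines**: the super-level set at a chosen height
  (default: the median, splitting the field in half) minus its 1-px
  8-connected erosion.  Theoretical dimension `D - 1`.

## Histology pipeline

Grayscale cores are binarised at a threshold, reduced to 1-px outlines
(mask minus erosion; bright-on-dark polarity by default, `--invert`
for the opposite stain convention), and the threshold is chosen to
maximise the mean `D_0` over a physical band — 10–50 µm by default for
optimisation, with group comparisons run on configurable bands such as
15–50 µm or 100–150 µm.  Both band conventions are plain configuration
values, not constants.  The scan uses 32 evenly spaced intensity
quantiles by default; levels whose outline is empty score `-inf` and
can never win, and exact ties resolve to the lowest level.  Per
subject (1–3 cores), the core with the greatest band-mean dimension is
kept, on the view that the most complex region of a heterogeneous
sample is the most informative one.  Groups are compared on per-subject
band means with the Kruskal–Wallis H test; the pairwise follow-up is a
Tukey–Kramer-type simultaneous comparison of rank means (studentized
range with infinite degrees of freedom, tie-corrected rank variance
`N(N+1)/12`), the construction used by the common statistical-toolbox
`multcompare` convention for rank tests.  Physical calibration
(`pixel_size`, µm/px) is required; for TMA-like fixtures a 600 µm core
diameter spanning the imaged core circle is the natural source for it.

**Synthetic cohorts.**  No patient data ships with the package.
`synthetic_cohort` builds seeded cohorts of Brownian-surface level-set
outlines with chosen theoretical dimensions (defaults 1.3 / 1.6 / 1.9,
20 subjects per grade, 257 px, 1.5 µm/px) and runs them through the
standard pipeline.  This emulates cohorts whose tissue outlines differ
in morphological complexity — the quantity the method actually
measures — and recovers the construction ordering with strongly
significant group separation.  It does *not* emulate staining
variability, illumination gradients, within-subject core
heterogeneity, or segmentation artifacts, so passing cohort tests
demonstrate the statistical pipeline, not clinical performance.

## Numerical choices and degenerate inputs

* Measure grids are validated to `|sum mu - 1| <= 1e-6` before entropy
  evaluation; zero-total images are rejected (measures undefined).
* LOWESS requires `degree + 1` points carrying weight above `1e-8`;
  thinner local designs raise a diagnostic rather than returning a
  rank-deficient solve.  Dimension curves need at least `degree + 2`
  scales.
* Ties: threshold optimisation and core selection both break ties
  toward the lowest candidate (level or index).
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical parameters and seed reproduce every fixture bit-for-bit,
  and CLI runs write a manifest with the effective configuration.

## Known limitations

* Large-scale estimates (`eps > side/8`) are quantisation-limited by
  the ragged-tile convention (see above): even a completely filled
  plane measures well below 2 there.  The documented approach of
  level-set outlines toward plane-filling behaviour is therefore
  observable in the mid-scale window (roughly 40–160 px on a 1025-px
  image) but not at `eps > 250 px`, where the box grid is 3–4 cells
  wide.
* Exactly self-similar renderings have discrete characteristic scales;
  with `sigma = 0.5` the dimension curve retains dips near them (the
  island's 20–50 px band mean above).  This is a property of the
  renderings, not estimator error, and larger `sigma` trades it
  against scale resolution.
* The Brownian kernel construction is exact for pair distances up to
  the unit square's side; statistics involving longer lags inherit the
  periodic embedding.
* Negative orders (`alpha < 0`) are numerically explosive on images
  with empty boxes and are disabled by default.
* Classical robustifying reweighting (bisquare iterations) of LOWESS
  is intentionally absent: the estimator is the single Gaussian-
  weighted fit, and outlier resistance comes from the bandwidth.
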