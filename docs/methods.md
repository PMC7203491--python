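# Methods

This package implements the statistical machinery of a cytoarchitectonic
gray-matter-density (GMD) analysis of a longitudinal AD/HC MRI cohort:
probability-weighted regional density extraction, within-session
test–retest reliability, random-coefficient models of decline, the
minimum interval at which a 0.5% density loss becomes statistically
detectable, and step-down multiplicity control. A synthetic cohort
generator with known ground truth stands in for the raw MRI, so every
stage is testable end to end without any download.

## Regional density extraction

A cytoarchitectonic probabilistic map assigns each voxel `v` a
probability `w_v ∈ [0,1]` of belonging to a microscopically defined
region (one map per hemisphere). Given a modulated voxelwise gray-matter
map `g`, the standardized regional density is the bilateral
probability-weighted mean

    GMD_region = (Σ_v g_v w_v^L + Σ_v g_v w_v^R) / (Σ_v w_v^L + Σ_v w_v^R),

with numerator and denominator pooled across hemispheres *before* the
division (a per-hemisphere variant exists but is non-default). The value
is linear in `g`, invariant to rescaling of the weights, and bounded by
the min/max of `g` on the union support — these invariants are enforced
by tests against an explicit per-voxel loop (agreement to 1e-12 relative
error).

Numerical/interface choices:

* Maps stored on a 0–100 scale are auto-rescaled to [0,1] on load
  (detected by `max > 1`); the quotient is scale-invariant but a fixed
  internal scale keeps invariants checkable.
* Atlas maps can be rigidly shifted (+4 mm y, +5 mm z by default in the
  CLI) to correct a template-convention offset; the shift is applied to
  the atlas affine, moving the maps toward the data, with both magnitude
  and sign configurable since the needed direction depends on which
  convention a given atlas release uses.
* A grid mismatch between the atlas and data is a hard error by default;
  nearest-neighbour resampling onto the data grid is available behind an
  explicit flag, because silent resampling hides registration bugs.
* Weighted voxels outside the gray-matter field of view contribute
  `g = 0` (modulated maps are defined everywhere).

## Synthetic cohort generator

The generator emulates a single-site longitudinal AD/HC study: visits at
months {0, 0.5, 1.5, 3.5, 6.5, 9.5, 12, 18, 24}, duplicate same-session
scans at months {0, 1.5, 9.5}, 41 AD and 21 HC subjects by default. Per
subject `i` and region `r` the latent trajectory is

    mu_ir(t) = (b_r d_i + u0_i) + (s_{r,g(i)} + u1_i) t,

with `b_r` the region's HC baseline, `d_i = 1` (HC) or
`1 − 0.191` (AD baseline deficit), `(u0_i, u1_i)` bivariate-normal
subject effects shared across regions, and group slopes
`s_{r,HC} = −0.0005 b_r` per month and `s_{r,AD} = s_{r,HC} (1 + 0.816)`.
Each scan observes `mu + ε` with `ε ~ N(0, (0.007 b_r)^2)` drawn
independently per scan; noise scales with the region baseline so
%-change statistics are comparable across regions. MMSE is linear per
group (AD slope −0.23 points/month, HC flat; baselines 19 and 29 —
separate group baselines because the study's inclusion criteria put AD
and HC on disjoint MMSE ranges), with N(0,1) noise, clamped to the
instrument's 0–30 range and left continuous (integer rounding would add
noise without changing any slope). Ages are N(69.1, 6.7²) truncated at
the 55-year inclusion floor.

Parameter provenance: group sizes, the visit schedule, the 19.1%
deficit, the 81.6% faster AD decline, the MMSE slopes and the age
distribution are anchored to the reference study population. The
variance components (`u0` SD 0.02, `u1` SD 0.0004/month, correlation
−0.3), the HC decline rate, and the within-session noise SD are
calibrated stand-ins: true values are not published, so they were chosen
once to put within-session reliability (ICC) in the observed high-0.9
range and a small "healthy-aging" decline in HC. They are configuration,
not findings.

What the generator does *not* emulate: scanner/field-strength effects,
registration error, nonlinear (e.g. accelerating) atrophy, informative
dropout (a uniform visit-dropout probability exists for robustness
checks only), and spatial correlation structure between regions beyond
the shared subject effects. Passing tests therefore demonstrate that the
estimators recover the truth of *this* linear-mixed world at the study's
design; they do not certify behavior under real-data artifacts.

## Test–retest reliability

Within-session agreement between the 1st and 2nd scans of a session is
quantified four ways, each per region unless noted:

* **% change model** — `100·(2nd − 1st)/1st` per subject-session; a
  linear mixed model with fixed HC mean and AD−HC difference and a
  per-subject random intercept (subjects contribute up to three
  sessions). Wald (normal) CIs and p-values; small-sample df corrections
  are out of scope. Each subject-session pair is treated as one
  exchangeable entity.
* **ICC** — one-way random-effects ICC(1),
  `(MSB − MSW)/(MSB + MSW)` for k = 2 replicates, chosen because
  replicate scans within a session are interchangeable (no rater or
  occasion effect); the exact F-based CI transforms
  `F0 = MSB/MSW` quantile limits with (n−1, n) df. Degenerate inputs:
  `MSW = 0` with between-subject spread gives ICC = 1 with CI [1,1];
  zero total variance is an error, never a NaN.
* **I2C2** — multivariate trace-ratio extension across all regions:
  `1 − tr(S_U)/tr(S_W)` with `tr(S_U)` the pooled within-subject
  (replicate-error) variance summed over regions and `tr(S_W)` the total
  variance of replicate-mean-centred data. It reduces exactly to the
  univariate ratio for one region. The CI is a subject-resampling
  percentile bootstrap (B = 1000 default, percentile rather than BCa for
  simplicity and reproducibility); a coverage simulation in the test
  suite shows this interval runs a few points below nominal (~90% at
  n = 100) for the trace ratio — the bootstrap understates the sampling
  SD because replicate noise is not redrawn within subjects.
* **Bland–Altman ratio** — log-ratios `ln(2nd/1st)`: geometric mean
  ratio `exp(mean)`, limits of agreement `exp(mean ± 1.96 SD)` (the
  1.96 multiplier is configurable), one-sample t-test against GMR = 1.

A coverage simulation of the % change model shows the HC-intercept CI is
conservative (~98% at 95% nominal) at this design: the true
random-intercept variance is zero and its REML estimate sits at the
boundary, inflating the intercept SE. The tests guard against
undercoverage, the harmful direction.

## Random-coefficient regression

Longitudinal decline is modelled per region by a linear mixed model with
per-subject random intercept and slope (unstructured 2×2 covariance,
REML): fixed effects are months since 1st MRI, group (HC reference),
group×time, age at 1st MRI (uncentred), and gender (female reference).
The intercept is then the age/gender-adjusted HC mean at the 1st MRI,
the group term the AD−HC baseline difference, and group×time the AD−HC
slope difference. Only the first scan of each session enters these fits;
replicates are reserved for the reliability analyses (they would deflate
the apparent residual variance unless a session effect were modelled).

Derived percentages follow the study's reporting style:
`baseline % lower = 100·(−β_group)/β_intercept` and
`% faster = 100·(slope_AD − slope_HC)/slope_HC` (positive = AD declines
faster when both slopes are negative); the latter is reported as
undefined when |slope_HC| falls below a configurable floor, since the
ratio explodes as the HC slope approaches zero.

Numerical choices: fixed-effect design columns are rescaled to unit
max-abs before optimization and estimates transformed back exactly
(months on 0–24 against densities near 0.5 otherwise put the variance
components ~7 orders of magnitude apart and stall quasi-Newton
optimizers); the optimizer chain is lbfgs → bfgs → powell; a singular
fitted random-effects covariance triggers a flagged refit with diagonal
covariance; exactly linear (noise-free) data are detected via a
zero-residual least-squares check and solved deterministically, because
the mixed likelihood degenerates when the residual variance is zero.
Inference is Wald with a normal/χ² reference throughout.

The MMSE trend model has group-specific intercepts and slopes with
random intercept + slope; group contrasts use Wald F (= z²) tests. The
change–change model regresses per-subject changes-from-baseline of MMSE
on changes of GMD with group-specific slopes and a random intercept.

## Detection interval

From the AD-only fit (intercept β0, slope β1 and their covariance), the
detection quantity at follow-up `t` months is
`Q(t) = 0.005·β0 + β1·t` with
`Var(Q) = 0.005²V(β0) + t²V(β1) + 2·0.005·t·Cov(β0,β1)`. The region's
detection time is the smallest point of the grid
{0.5, 1.0, …, 24.0} at which the upper 95% confidence limit of `Q(t)`
is negative; "not detectable" if none. The 0.5% threshold, the grid, the
confidence level and the z-multiplier (1.96 by default; a t-quantile
could be substituted) are all configurable, and the β0–β1 covariance is
included by default with a diagonal-only option. Tests verify the grid
scan against the closed-form root of `Q(t) + z·SE(t) = 0` and the
monotonicity of the detection time in β1.

## Multiplicity control

The per-rank thresholds printed alongside published within-session
p-value families follow the Holm-type step-down sequence
`α/(m − k + 1)` for ascending ranks `k = 1..m`, not the textbook
Benjamini–Hochberg `α·k/m`, despite being labelled an FDR procedure in
the source tables. The default method (`paper_stepdown`) reproduces the
printed cells; `bh_classic` is selectable. The rejection rule is
step-down: reject the longest prefix of sorted p-values meeting every
threshold up to its rank; ties are broken by stable input order.
Comparisons against printed cells round half-up to the displayed digits
(builtin `round` is half-to-even and disagrees at e.g. 0.003125).

## Problem sizes and reproducibility

The analysis drivers run the full 27-region cohort at the study's group
sizes. Simulation-based calibration tests use deliberately compact
designs — 200 replicate cohorts of 30+30 subjects for the group×time
bias and type-I checks, 200 subjects for I2C2 recovery, 100 replications
for coverage — sizes at which Monte-Carlo error is small relative to the
asserted bands. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; pipeline runs with the same config and seed
produce byte-identical outputs, and each run writes a manifest recording
versions, seed, α, method and a config hash.

## Known limitations

* Inference is asymptotic (Wald/normal); no Kenward–Roger or
  Satterthwaite small-sample df corrections.
* The percentile bootstrap for I2C2 undercovers slightly (documented
  above); BCa or a within-subject residual bootstrap could close the gap.
* The generator's linear trajectories cannot probe sensitivity to
  nonlinear atrophy, and its region-level noise ignores spatial
  correlation beyond shared subject effects.
* The `% faster` contrast is a ratio of estimated slopes and is unstable
  whenever the HC slope is near zero; single-cohort estimates can sit
  far from truth even when both slope estimates are individually
  well-behaved.
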