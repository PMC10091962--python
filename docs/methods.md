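# Methods

`hybridspace` quantifies whether an experimental hybrid cross produces more
phenotypic variation — or genuinely novel trait combinations — than its two
parental species. It was built around a crossing design with two parental
groups (P1, P2) and reciprocal F1 and F2 hybrid groups (encoded
mother×father), with two kinds of phenotype: brain morphometrics and
learning performance. Everything below is the package's own account of what
it computes and why.

## Trait spaces

**Brain morphospace (3-D).** Brain-region volumes are estimated from linear
dimensions with the ellipsoid formula V = L·W·H·π/6. All size variables are
log10-transformed, which linearises allometric scaling. "Relative" traits
are residuals from pooled ordinary-least-squares fits across all groups and
both sexes:

* axis 1 — residual of log10 brain weight (mg) on log10 body length (mm);
* axes 2–3 — residuals of log10 telencephalon and optic-tectum volume (mm³)
  on log10 brain-remainder volume, where total brain volume is the sum of
  the six measured region volumes and the remainder subtracts the focal
  region (so a region never appears in its own covariate).

A single pooled fit (rather than per-group fits) is a deliberate choice: it
gives every individual a residual on a common scale, which is what a shared
trait space requires. Per-group allometric slopes are the right tool for
*inference about group differences*, not for constructing the space, and
are out of scope here. Residual axes have mean zero by construction;
group structure appears as group mean offsets.

**Cognitive space (2-D).** Axes are log10 trials-to-criterion in an
associative colour-discrimination task and a subsequent reversal task.
Only individuals that reached criterion in both tasks enter the space;
everyone else is listed in an exclusion report with the failing task named.

## Learning-criterion scoring

The criterion is the first run of seven consecutive correct choices
(binomially significant against chance at p = 0.5). The score is the
1-based index of the trial on which that run completes. Runs completing
after the task maximum (40 trials associative, 60 reversal; configurable)
do not count, and such fish are censored. The protocol's minimum trial
counts gate phase transitions in the assay, not the score, so the raw
completion index is used. Success-rate percentages are rounded half-up to
integers, matching conventional reporting (19/24 → 79%).

## KDE dispersion and the 95% region

Each group's trait cloud is smoothed with a Gaussian product kernel with a
diagonal (axis-aligned) bandwidth

    h_j = c* · σ_j · n^(−1/(d+4)),

where σ_j is the per-axis sample SD and the single scale factor c* is
selected by least-squares cross-validation (closed-form criterion for the
Gaussian kernel) over 25 log-spaced values c ∈ [0.25, 4]. A one-parameter
grid search is deterministic and reproducible; a full unconstrained
bandwidth matrix adds tuning freedom without changing what the statistic
measures. Ties break toward the smaller factor.

**Contour threshold.** The 95% region is the density superlevel set
{x : f̂(x) ≥ t} with t the 5% empirical quantile (linear interpolation
between order statistics) of the **leave-one-out** densities at the group's
own points. Using leave-one-out evaluation matters: a point's own kernel
inflates its density estimate, and a threshold taken from self-inclusive
densities is systematically too high for fresh draws — a test sample from
the very distribution that generated the group would then fall "outside"
the 95% region at roughly 13% per parent rather than ~5%. With the
leave-one-out threshold the region's coverage is calibrated for the
population, which is the property the 5%-by-chance baseline logic relies
on. A side effect is that slightly more than 95% of the training points
themselves satisfy the membership test (their self-inclusive densities can
only be higher).

**Hypervolume.** Dispersion is the Lebesgue measure of the 95% region,
counted on a rectangular evaluation grid (cells whose centre density
reaches the threshold × cell volume). Defaults: 151 points per axis in 2-D,
101 in 3-D, grid padded by 4 bandwidths beyond the data range — about 10⁶
cells in 3-D, enough that the gridded density integrates to 1 within ±2%
and refinement changes the volume by well under 5%. Membership queries for
arbitrary points evaluate the kernel sum exactly instead of interpolating
from the grid, removing one approximation knob.

## Transgression

A hybrid is transgressive when it lies outside the 95% regions of *both*
parents. Individuals are classified independently; no multiplicity
correction is applied because frequencies are compared against the chance
baseline rather than tested per fish. `chance_rate_simulation` measures
that baseline: parents and test points drawn from one common distribution
give a mean transgressive rate close to (slightly below) 5% — below,
because a point must escape two highly overlapping regions at once.

## Simulated-hybrid null and mean-phenotype geometry

To ask whether a hybrid group's *mean* phenotype is what additive
inheritance predicts, the package resamples midparent phenotypes: each
simulated hybrid is the coordinate-wise mean of one random P1 individual
and one random P2 individual (independent, uniform, with replacement —
with-replacement keeps replicates i.i.d.). Replicates (default 100) of
populations matched to the experimental group sizes (default 35 for brain
traits, 25 for cognition) yield null distributions for three statistics:

* **hypervolume** of the replicate's 95% KDE region;
* **parental bias** — |(h − M)·u|: deviation of the mean phenotype h from
  the midparent midpoint M along the unit inter-parental axis u, reported
  as a magnitude plus a direction (toward P1 / toward P2);
* **phenotypic mismatch** — the perpendicular distance of h from the
  infinite line through the parental means. The infinite line (not the
  segment) keeps the along-axis and off-axis components orthogonal even for
  means beyond a parent; bias² + mismatch² = ‖h − M‖² exactly.

Observed statistics are placed in the null as empirical percentiles
(midrank convention for ties), with a flag when they fall outside the
central 95% of replicates. Replicate r uses an RNG substream derived from
(seed, r), so any single replicate can be regenerated.

## Synthetic data generator

The generator is the package's test bed and defines the study conditions
under which its guarantees are demonstrated:

* parents: d-variate normals (default d = 3, unit covariances, means 2 SD
  apart on the first axis — clearly distinct but overlapping species);
* F1 groups: mean = midparent + heterosis + the component of a configured
  mismatch vector orthogonal to the parental axis (projected before
  injection, so the ground-truth mismatch magnitude is exact); covariance
  (Σ₁+Σ₂)/4, the variance of a midparent of independent draws;
* F2 groups: same mean without heterosis; covariance scaled by a scalar
  `segregation_factor` (default 1.0 — segregation variance is a knob, not a
  baked-in assumption);
* optional transgression injection: each hybrid is displaced by a fixed
  vector with a configured Bernoulli probability, so injected transgressive
  fractions carry binomial sampling noise like real ones;
* defaults of 40 fish per group match pooled-sex brain-trait group sizes.

Trial logs come from per-fish Bernoulli learning curves,
P(correct at t) = logistic(a + uᵢ + b·t) with uᵢ ~ N(0, sd²); defaults
(a = 0, b = 0.12, sd = 0.5, 25 fish per group) give high success within the
40-trial window, as in the assays the package targets. The generator stops
a fish at criterion and runs the reversal task only for associative
passers, reproducing the assay's censoring structure.

What the generator does *not* emulate: real measurement error structure,
genetic architecture (no loci, dominance, or epistasis), sex differences,
non-Gaussian trait distributions, or session/day structure in the trials.
Passing tests therefore demonstrate correctness of the statistics under a
clean phenotypic model, not robustness to every artefact of real data.

## Numerical choices and degenerate inputs

* Log base 10 throughout (conventional in allometry; base changes scale
  only).
* Zero-variance axes, non-positive-definite covariances, empty groups,
  non-contiguous trial indices, and non-binary outcomes are hard errors,
  not silent fixes; undefined percentages (0/0) are reported missing, never 0.
* Coincident parental means make the inter-parental axis undefined and
  raise an error rather than returning 0.
* A single-point KDE falls back to the self-inclusive density for its
  threshold (leave-one-out is undefined at n = 1).
* Bias direction uses a 1e-12 dead zone around zero projection.

## Problem sizes used in the test suite

The suite exercises the full pipeline at reduced problem sizes chosen to
keep every Monte-Carlo check at ≥3-SE resolution: KDE oracle n = 2000,
chance-baseline 50 replicates × 1000 test points, mismatch recovery 200
replicate cohorts of 50 fish per group, learning fuzzing 1000 sequences.
These are the package's reference conditions; all scale up by argument.

## Known limitations

* The hypervolume depends (weakly) on grid resolution; the reported value
  should always be read with the grid used, which the model serialises.
* LSCV bandwidth selection is noisy at very small n (< ~20); the factor
  grid bounds how wild it can get but small-sample hypervolumes are
  dominated by bandwidth, not data.
* The chance transgression baseline sits nearer 3.5–4% than the nominal 5%
  because escaping both parental regions is harder than escaping one; the
  package reports the measured rate rather than asserting the nominal one.
* Percentiles from 100 replicates have a resolution of 0.5 points; flags
  at the 2.5/97.5 boundaries should not be over-read.
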