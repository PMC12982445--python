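# Methods

## The statistic

Every quantity this package produces derives from one statistic: Cohen's d
for a male/female comparison with an equal-weight pooled standard deviation,

    d = (x̄_M − x̄_F) / √((SD_M² + SD_F²) / 2),

with females as the reference group, so d > 0 means the male mean is larger.
The denominator is the root-mean-square of the two group SDs — *not* the
sample-size-weighted (Hedges) pooled SD.  This choice is deliberate and
load-bearing: growth-chart sources publish per-age moments without per-age
counts, so the n-weighted denominator is not generally computable, and using
one formula everywhere keeps the three tiers comparable.  Hedges' small-sample
correction and Glass's Δ are out of scope for the same reason.

Each trajectory point carries the numerator (mean difference, metric units)
and the denominator (pooled SD) alongside d, because a change in d can be
driven by either: a widening mean gap or a shrinking spread.

The large-sample sampling variance

    var(d̂) ≈ (n_M + n_F)/(n_M·n_F) + d²/(2(n_M + n_F))

is attached as metadata wherever counts are known.  It is never used to
filter points; the only confidence rule is the total-count threshold below.

`superiority_accuracy(d)` returns 100·Φ(d/√2), the probability that a random
member of the higher-mean group exceeds a random member of the other group
(the "common-language effect size") for two unit-variance normals separated
by d.  It is the transform under which d = 2.13 corresponds to ≈ 93.4%,
the figure often quoted as a "linear classifier accuracy" for effects of
that size.  Note this is *not* the optimal-Bayes linear classifier accuracy,
which is Φ(d/2) ≈ 85.7% at d = 2.13; the quoted 93.3% figure is only
reproduced by the probability-of-superiority transform, so that is what the
function implements, with the naming kept honest.

## Chart-tier extraction

Centile charts are read in a single long-format CSV schema
(`source,tier,age,age_unit,sex,p50,sd,p_lo,rank_lo,p_hi,rank_hi`).  Per row,
the 50th percentile is taken as the mean (a normality assumption; no
median-skew correction is applied) and the SD is taken directly when
published, otherwise back-calculated from a symmetric outer-centile pair:

    SD = (p_hi − p_lo) / (z(rank_hi/100) − z(rank_lo/100)).

Asymmetric centile layouts are rejected rather than approximated — they
signal a skewed (LMS-type) reference, and refitting such models is out of
scope.

Sources that publish regression equations instead of tables are described
by per-sex polynomial coefficient lists for mean(age) and SD(age) with a
valid age range (YAML); evaluation outside the range raises rather than
extrapolates, and an SD polynomial that is not strictly positive on the
range is rejected at construction.

Epochs are matched across sexes exactly on the printed age value — every
supported reference tabulates both sexes on the same weekly/monthly grid —
and epochs present in only one sex are skipped with a log message, never
interpolated.

## Sliding-window engine (individual-level tier)

Cross-sectional subjects are binned into half-open windows [lo, lo+w) of
width w = 4 years advanced by 2-year steps, starting at age 4; the window
grid extends while the window start is below the oldest subject, so trailing
windows may be partially (or not at all) populated.  Half-open intervals
prevent double counting at even ages; with width = 2·step every subject
strictly interior to the grid contributes to exactly two windows, which is
the intended smoothing.  Each window's per-sex mean and SD (ddof = 1) feed
the statistic above; the point sits at the window centre.

Two flags qualify each point:

* `defined = False` when either sex has fewer than two members in the window
  (an SD needs n ≥ 2) or both within-window SDs vanish; undefined points
  carry no statistics but keep their counts.
* `low_confidence = True` when the window total n_M + n_F falls below 60
  (configurable).  Low-confidence points are reported and plotted in a
  distinct hollow style, never dropped.

Because a window's SD mixes measurement spread with growth across the
window's 4-year span, windowed d̂ is slightly attenuated where the mean
curve is steep relative to the between-subject SD; for cortical metrics the
age trend over 4 years is small against the population SD, so the
attenuation is below ~2% in the default scenario (it is an inherent property
of the method, not of this implementation).

Leave-one-dataset-out sensitivity reruns the full trajectory once per
contributing dataset, holding the window grid fixed to the full-data grid so
trajectories are comparable point-by-point.

## Common lifespan axis

The three tiers report ages in gestational weeks, postnatal months, and
years.  They are juxtaposed on post-conception days with a fixed 280-day
term:

    prenatal   days = weeks × 7
    postnatal  days = 280 + months × 365.25/12
    mri        days = 280 + years × 365.25

This makes the prenatal/postnatal junction exact (week 40 and month 0
coincide) and a logarithmic axis meaningful.  The fixed month length
(30.4375 days) trades calendar fidelity for determinism.  Combining series
is pure concatenation grouped by (tier, metric, source) — no cross-tier
interpolation, averaging, or smoothing.  Tidy CSVs format floats with 9
significant digits, which makes repeated writes of the same analysis
byte-identical.  Default demarcated ticks on the combined figure are birth
and 1, 5, 10, 25, 50, 90 years (configurable).

## Synthetic cohorts

The generator is the test bed standing in for the source data, and its
construction is matched to the statistic: both sexes share an SD curve
σ(age), and the male mean is placed at μ_F(age) + d(age)·σ(age).  With
equal per-sex SDs the pooled SD *is* σ(age), so the generating piecewise-
linear trajectory d(age) is exactly the quantity the pipeline estimates —
no distributional subtlety separates truth from target.  An unequal-SD
stress mode (male SD inflated by a factor) is available; there the recovered
d targets the formula's value, not a distributional effect size.

Noiseless charts (P50 = per-sex mean, SD = σ) are recovered exactly, to
float precision; subject-level cohorts are recovered statistically, with
per-window standard error √(4/n + d²/2n).

The default "lifespan" scenario encodes the canonical shape of these
trajectories: prenatal head-circumference d between 0.3 and 0.5 with a mild
bump near gestational week 25; a postnatal rise to d = 1.1 at month 10
followed by decline through early childhood; cortical volume/surface area
rising from 0.4 at age 5 to 1.4 at 24, plateauing, with a gentle decline
after ~43 (so the mean CV effect size over ages 4–70 comes out near 1.25);
cortical thickness negative (female-greater) in childhood, crossing zero
near 13.  Mean curves and SDs are realistic in scale (head circumference in
cm against WHO-like magnitudes; cortical volume ≈ 4.5–5.1 × 10⁵ mm³ with
SD 4.8 × 10⁴; thickness ≈ 2.4–2.7 mm with SD 0.11; ICV ≈ 1.25–1.38 × 10⁶ mm³),
and sex ratios sit near parity per tier (male fraction 0.502–0.526).  The
default MRI cohort size, 25,846, mirrors the roster total in `cohorts`.

Subject-level records carry all four metrics.  Cortical volume is drawn
from its model, thickness from its own model, and surface area is defined
as CV/CT so the per-subject product SA × CT carries the configured CV
trajectory exactly; ICV is drawn independently.  What the generator does
*not* emulate: scanner/site effects, non-Gaussian metric distributions,
cross-metric correlation beyond the SA = CV/CT identity, and longitudinal
within-subject correlation.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery under idealised sampling, not
robustness to the heterogeneity of real multi-site data (a `study_mix`
layout with roster-proportional dataset sizes and age ranges provides a
first-order heterogeneity stress).

## Validation experiment sizes

* **Oracle equivalence** — 1,000 random records; every defined window's
  d, mean difference and pooled SD must match a pure-Python from-scratch
  recomputation to 1e-12 relative.  The oracle uses exact-rational
  `statistics` arithmetic, so this bounds the numpy path's summation error.
* **Parameter recovery** — 600,000 subjects uniform on ages [4, 90) with
  trajectory (5, 0.4) → (24, 1.4) → (89, 1.4), ≈ 28,000 per window.  At that
  n the per-window standard error (≈ 0.013 at d = 1.4) plus the worst
  intrinsic window-averaging bias (≈ 0.026, at the window straddling the
  slope change at age 24: the window average of a piecewise-linear d differs
  from its centre value there) sits well inside the 0.07 acceptance band.
* **Null calibration** — 50,000 subjects with d ≡ 0 on ages [20, 28) with a
  fixed grid of three fully covered windows (≈ 25,000 subjects each), so the
  |d̂| < 0.03 bound corresponds to > 3 standard errors per window; the
  fraction of windows within 2·SE is reported alongside.
* **Bootstrap check of var(d̂)** — n = 200 per sex, 2,000 resamples,
  15% relative agreement.

Seeds are fixed in tests (derandomised hypothesis profile included) and
derived from the single `--seed` argument in `scripts/acceptance.py`, which
reruns all of the above from scratch.

## Known limitations

* P50-as-mean is exact only under symmetry; real growth references built on
  skewed (LMS) models introduce a small bias the chart tier inherits.
* The window engine reports no uncertainty band on the trajectory itself;
  var(d̂) metadata and the n < 60 flag are the only confidence signals,
  matching the reporting style the pipeline emulates.
* The common axis treats every birth as full-term (280 days); preterm
  heterogeneity is not represented.
* Baseline-only selection keeps the earliest-age row per subject and assumes
  subject ids are unique within and across the datasets of one table.
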