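# lifespan-d

Sex differences in global brain size are present from mid-gestation onward,
but they are not constant: the standardized male–female gap widens, peaks,
shrinks and widens again at different life stages.  `lifespan-d` is a
pipeline for quantifying that variation.  It turns three kinds of source
data — published growth-chart tables (head circumference by gestational
week or postnatal month), sex-specific mean/SD regression equations, and
individual-level cortical morphometry exports (total surface area, mean
thickness, ICV) — into harmonized trajectories of Cohen's d across the
lifespan, for researchers in developmental neuroscience, biostatistics and
epidemiology who need effect-size curves rather than raw growth curves.

Every estimate is the pooled-SD Cohen's d

```
d = (x̄_M − x̄_F) / √((SD_M² + SD_F²) / 2)
```

(females as reference; d > 0 ⇔ males larger), reported together with its
numerator (mean difference) and denominator (pooled SD).  Chart tiers yield
one point per printed epoch, taking the 50th percentile as the mean and
back-calculating the SD from outer centiles when necessary.  The
individual-level tier uses a sliding window — width 4 years, step 2 years,
starting at age 4 — computing per-sex moments within each half-open window;
windows with total n < 60 are flagged low-confidence, and cortical volume is
derived per subject as surface area × mean thickness.  All tiers are mapped
onto a common post-conception-day axis (term = 280 days) for a single
log-scale lifespan figure.

A synthetic-cohort generator with a known piecewise-linear ground-truth
d(age) makes every stage testable end to end: noiseless charts are recovered
exactly, subject-level cohorts statistically, and leave-one-dataset-out
sensitivity reruns quantify single-source influence.

## Worked example

```python
from lifespan_d import (chart_effect_trajectory, superiority_accuracy,
                        windowed_effects)
from lifespan_d.synthetic_cohort import (lifespan_preset, simulate_chart,
                                         simulate_subjects)

models = lifespan_preset(n_mri=25_846)

# chart tier: noiseless postnatal head-circumference chart, one row per sex per month
rows = simulate_chart(models["postnatal"], range(0, 85), tier="postnatal")
traj = chart_effect_trajectory([r for r in rows if r.sex == "M"],
                               [r for r in rows if r.sex == "F"])
peak = max(traj, key=lambda p: p.d)
print(f"postnatal peak: d = {peak.d:.3f} at month {peak.age:.0f}")

# individual-level tier: sliding-window cortical-volume trajectory
records = simulate_subjects(models["mri_cv"], (5.0, 89.0), seed=17,
                            ct_model=models["mri_ct"])
points = windowed_effects(records, "CV")
for p in points[:3] + points[9:11]:
    print(f"window centre {p.age:4.0f} y  d = {p.d:5.2f}  "
          f"(n = {p.n_m + p.n_f}, low confidence: {p.low_confidence})")

print(f"implied superiority accuracy at d = 2.13: "
      f"{superiority_accuracy(2.13):.1f}%")
```

prints

```
postnatal peak: d = 1.100 at month 10
window centre    6 y  d =  0.47  (n = 920, low confidence: False)
window centre    8 y  d =  0.53  (n = 1267, low confidence: False)
window centre   10 y  d =  0.73  (n = 1256, low confidence: False)
window centre   24 y  d =  1.48  (n = 1171, low confidence: False)
window centre   26 y  d =  1.52  (n = 1236, low confidence: False)
implied superiority accuracy at d = 2.13: 93.4%
```

The chart route recovers the generating peak (d = 1.1 at month 10) exactly
because chart moments are noiseless; the windowed estimates scatter around
the generating curve (0.4 at age 5 rising to a 1.4 plateau at 24) with
standard error ≈ √(4/n) per window — at ~1,200 subjects per window,
individual points land within roughly ±0.1 of the curve, as above.  The
last line is the probability-of-superiority transform 100·Φ(d/√2): the
chance a random male value exceeds a random female value when the groups
are separated by d.

The same pipeline runs from the shell on CSV inputs:

```
lifespan-d simulate --n 25846 --seed 17 --out sim/
lifespan-d postnatal --chart sim/postnatal_chart.csv --out postnatal.csv
lifespan-d mri --subjects sim/subjects.csv --metric CV --out mri_cv.csv
lifespan-d combine --in postnatal.csv --in mri_cv.csv --out lifespan.csv --fig figures/
```

`combine` writes a tidy CSV (one row per trajectory point, with the common
axis in post-conception days) and renders per-tier d / mean-difference /
pooled-SD panels plus the combined log-axis lifespan figure.

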