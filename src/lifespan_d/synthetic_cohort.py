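"""Synthetic cohorts with a known ground-truth sex-difference trajectory.

Every stage of the pipeline is exercised against data whose generating
effect size d(age) is known exactly.  The construction mirrors how the
pooled-SD Cohen's d behaves: both sexes share an SD curve σ(age), the
female mean follows a parametric growth curve μ_F(age), and the male mean
is placed at

    μ_M(age) = μ_F(age) + d(age) · σ(age),

so with equal per-sex SDs the pooled SD equals σ(age) and the generating
d(age) is exactly the statistic the pipeline estimates.  d(age) is a
piecewise-linear trajectory over control points, clamped outside them.

Two output shapes:

* ``simulate_chart`` — noiseless centile-chart rows (P50 = per-sex mean,
  SD = σ), from which the chart pipeline recovers d(age) to float precision.
* ``simulate_subjects`` — individual-level records with Gaussian noise,
  unequal per-dataset sizes and near-parity sex ratios, from which the
  sliding-window engine recovers d(age) statistically.

For subject-level cohorts the primary model drives cortical volume; a
companion model drives mean thickness (its trajectory may be negative in
childhood, the female-greater regime), and surface area is derived as
CV / CT so that the per-subject product SA × CT carries the configured CV
trajectory exactly.  An optional third model drives ICV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import cohorts
from .chart_ingest import ChartRow, RegressionSpec
from .errors import ConfigurationError, InvalidSpecError
from .morphometry_ingest import SubjectRecord

__all__ = [
    "Curve",
    "TrajectorySpec",
    "GrowthModel",
    "true_d",
    "simulate_subjects",
    "simulate_chart",
    "regression_specs_from_model",
    "model_from_config",
    "lifespan_preset",
    "table1_dataset_layout",
    "LIFESPAN_PRESET_CONFIG",
]


@dataclass(frozen=True)
class Curve:
    """A parametric curve of age: constant, polynomial, logistic or
    piecewise-linear.  Callable on scalars or arrays."""

    kind: str
    params: tuple

    @staticmethod
    def constant(value: float) -> "Curve":
        return Curve("constant", (float(value),))

    @staticmethod
    def polynomial(coeffs: Sequence[float]) -> "Curve":
        """Ascending-order coefficients c0 + c1·x + c2·x² + ..."""
        return Curve("polynomial", tuple(float(c) for c in coeffs))

    @staticmethod
    def logistic(offset: float, scale: float, rate: float, midpoint: float) -> "Curve":
        """offset + scale / (1 + exp(−rate·(x − midpoint)))."""
        return Curve("logistic", (float(offset), float(scale), float(rate), float(midpoint)))

    @staticmethod
    def piecewise_linear(points: Sequence[Sequence[float]]) -> "Curve":
        """Linear interpolation through (age, value) anchors, clamped outside."""
        ages = [float(a) for a, _ in points]
        if any(b <= a for a, b in zip(ages, ages[1:])) or len(ages) < 2:
            raise InvalidSpecError("anchor ages must be strictly increasing (>= 2 anchors)")
        return Curve("piecewise_linear", tuple((float(a), float(v)) for a, v in points))

    def __call__(self, age):
        x = np.asarray(age, dtype=float)
        if self.kind == "constant":
            out = np.full_like(x, self.params[0])
        elif self.kind == "polynomial":
            out = np.polynomial.polynomial.polyval(x, np.asarray(self.params))
        elif self.kind == "logistic":
            offset, scale, rate, midpoint = self.params
            out = offset + scale / (1.0 + np.exp(-rate * (x - midpoint)))
        elif self.kind == "piecewise_linear":
            xs = np.array([a for a, _ in self.params])
            ys = np.array([v for _, v in self.params])
            out = np.interp(x, xs, ys)
        else:  # pragma: no cover - constructors prevent this
            raise ConfigurationError(f"unknown curve kind {self.kind!r}")
        return float(out) if np.isscalar(age) else out


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth d(age) as piecewise-linear control points, clamped
    outside the control range."""

    control_points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.control_points]
        if len(ages) < 1 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise InvalidSpecError("control ages must be strictly increasing")

    def __call__(self, age):
        xs = np.array([a for a, _ in self.control_points])
        ys = np.array([d for _, d in self.control_points])
        out = np.interp(np.asarray(age, dtype=float), xs, ys)
        return float(out) if np.isscalar(age) else out


def true_d(spec: TrajectorySpec, age) -> float:
    """Evaluate the ground-truth trajectory at one or many ages."""
    return spec(age)


@dataclass(frozen=True)
class GrowthModel:
    """Generating model for one metric: μ_F(age), shared σ(age), d(age).

    ``sex_ratio`` is the probability a simulated subject is male;
    ``dataset_sizes`` maps dataset id → subject count.  ``unequal_sd``
    optionally inflates the male SD by a factor (stress mode; the recovered
    d then targets the pooled-SD formula's value, not a distributional d).
    """

    female_mean: Curve
    sd_curve: Curve
    trajectory: TrajectorySpec
    sex_ratio: float = 0.5
    dataset_sizes: Mapping[str, int] = field(default_factory=lambda: {"synthetic": 1000})
    metric: str = "CV"
    unequal_sd: float = 1.0  # male SD multiplier

    def __post_init__(self) -> None:
        if not 0.0 < self.sex_ratio < 1.0:
            raise ConfigurationError(f"sex_ratio must be in (0, 1), got {self.sex_ratio}")
        if any(n <= 0 for n in self.dataset_sizes.values()):
            raise ConfigurationError("dataset sizes must be positive")
        if self.unequal_sd <= 0:
            raise ConfigurationError("unequal_sd multiplier must be > 0")

    def male_mean(self, age):
        return self.female_mean(age) + self.trajectory(age) * self.sd_curve(age)

    def mean(self, age, sex: str):
        return self.male_mean(age) if sex == "M" else self.female_mean(age)

    def sd(self, age, sex: str = "F"):
        base = self.sd_curve(age)
        return base * self.unequal_sd if sex == "M" else base


def simulate_subjects(
    model: GrowthModel,
    ages: tuple[float, float],
    seed: int,
    ct_model: GrowthModel | None = None,
    icv_model: GrowthModel | None = None,
    dataset_age_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[SubjectRecord]:
    """Draw an individual-level cohort from the generating model.

    Per dataset, ages are uniform on that dataset's range (default: the
    global ``ages`` range), sex is Bernoulli(sex_ratio), and each metric is
    Gaussian with the model's sex-specific mean and SD at the subject's
    age.  ``model`` drives cortical volume; ``ct_model`` (a default flat
    thickness model if omitted) drives mean thickness; surface area is
    CV / CT.  Reproducible for a given seed.
    """
    lo, hi = float(ages[0]), float(ages[1])
    if not lo < hi:
        raise ConfigurationError(f"age range must have lo < hi, got {ages}")
    if ct_model is None:
        ct_model = GrowthModel(
            female_mean=Curve.constant(2.5),
            sd_curve=Curve.constant(0.11),
            trajectory=TrajectorySpec(((0.0, 0.0),)),
            sex_ratio=model.sex_ratio,
            metric="CT",
        )
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    for ds in sorted(model.dataset_sizes):
        n = int(model.dataset_sizes[ds])
        ds_lo, ds_hi = (dataset_age_ranges or {}).get(ds, (lo, hi))
        age = rng.uniform(ds_lo, ds_hi, size=n)
        male = rng.random(n) < model.sex_ratio
        cv = _draw_metric(rng, model, age, male)
        ct = _draw_metric(rng, ct_model, age, male)
        if np.any(cv <= 0) or np.any(ct <= 0):
            raise ConfigurationError(
                "model produced non-positive cortical volume or thickness; "
                "means are too close to zero relative to the SD curve"
            )
        sa = cv / ct
        icv = _draw_metric(rng, icv_model, age, male) if icv_model is not None else None
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{ds}_{i:06d}",
                    dataset_id=ds,
                    sex="M" if male[i] else "F",
                    age=float(age[i]),
                    surface_area=float(sa[i]),
                    mean_thickness=float(ct[i]),
                    icv=float(icv[i]) if icv is not None else None,
                )
            )
    return records


def _draw_metric(rng, model: GrowthModel, age: np.ndarray, male: np.ndarray) -> np.ndarray:
    mean = np.where(male, model.male_mean(age), model.female_mean(age))
    sd = np.asarray(model.sd_curve(age)) * np.where(male, model.unequal_sd, 1.0)
    if np.any(sd <= 0):
        raise ConfigurationError("sd_curve must be strictly positive over the age range")
    return rng.normal(mean, sd)


def simulate_chart(
    model: GrowthModel,
    epochs: Sequence[float],
    tier: str,
    source: str = "synthetic",
) -> list[ChartRow]:
    """Noiseless centile-chart rows: P50 = per-sex mean, SD = σ(age).

    Two rows (M, F) per epoch.  Running the chart pipeline on the output
    recovers the generating d(age) exactly (equal per-sex SDs make the
    pooled SD equal σ, so the quotient collapses to d).
    """
    if len(epochs) == 0:
        raise ConfigurationError("need at least one epoch")
    unit = {"prenatal": "week", "postnatal": "month", "mri": "year"}[tier]
    rows: list[ChartRow] = []
    for age in epochs:
        sd = float(model.sd_curve(age))
        for sex in ("M", "F"):
            rows.append(
                ChartRow(
                    age=float(age), sex=sex, p50=float(model.mean(age, sex)),
                    sd=sd * (model.unequal_sd if sex == "M" else 1.0),
                    source=source, tier=tier, age_unit=unit,
                )
            )
    return rows


def regression_specs_from_model(
    model: GrowthModel,
    valid_age_range: tuple[float, float],
    degree: int = 3,
    n_grid: int = 101,
) -> tuple[RegressionSpec, RegressionSpec]:
    """Emulate a source that publishes regression equations instead of tables.

    Fits polynomials of the given degree to the model's sex-specific mean
    and SD curves over the range and returns (male, female) specs.  For
    polynomial model curves of degree <= ``degree`` the fit is exact.
    """
    lo, hi = valid_age_range
    grid = np.linspace(lo, hi, n_grid)
    specs = []
    for sex in ("M", "F"):
        mean_fit = np.polynomial.Polynomial.fit(grid, model.mean(grid, sex), degree).convert()
        sd_fit = np.polynomial.Polynomial.fit(grid, np.broadcast_to(model.sd(grid, sex), grid.shape), degree).convert()
        specs.append(
            RegressionSpec(
                sex=sex,
                mean_coeffs=tuple(mean_fit.coef),
                sd_coeffs=tuple(sd_fit.coef),
                valid_age_range=(float(lo), float(hi)),
            )
        )
    return specs[0], specs[1]


# --------------------------------------------------------------------------
# presets

_CURVE_BUILDERS = {
    "constant": lambda p: Curve.constant(p["value"]),
    "polynomial": lambda p: Curve.polynomial(p["coeffs"]),
    "logistic": lambda p: Curve.logistic(p["offset"], p["scale"], p["rate"], p["midpoint"]),
    "piecewise_linear": lambda p: Curve.piecewise_linear(p["points"]),
}


def _curve_from_config(cfg: Mapping) -> Curve:
    try:
        builder = _CURVE_BUILDERS[cfg["kind"]]
    except KeyError as exc:
        raise ConfigurationError(f"unknown or missing curve kind in {cfg!r}") from exc
    return builder(cfg)


def model_from_config(cfg: Mapping) -> GrowthModel:
    """Build a GrowthModel from a plain config document (YAML-compatible)."""
    return GrowthModel(
        female_mean=_curve_from_config(cfg["female_mean"]),
        sd_curve=_curve_from_config(cfg["sd_curve"]),
        trajectory=TrajectorySpec(tuple((float(a), float(d)) for a, d in cfg["trajectory"])),
        sex_ratio=float(cfg.get("sex_ratio", 0.5)),
        dataset_sizes=dict(cfg.get("dataset_sizes", {"synthetic": 1000})),
        metric=str(cfg.get("metric", "CV")),
        unequal_sd=float(cfg.get("unequal_sd", 1.0)),
    )


#: Default lifespan scenario.  Head-circumference values are in cm; cortical
#: metrics in mm²/mm/mm³.  The d trajectories encode the canonical lifespan
#: shape: a modest prenatal effect (~0.3–0.5) with a bump near week 25, a
#: postnatal rise to d ≈ 1.1 at month 10 followed by decline, a cortical
#: volume/surface-area rise from ~0.4 at age 5 to ~1.4 at 24 with a plateau
#: and gentle decline after ~43, and a thickness effect that is negative
#: (female-greater) in childhood, crossing zero near age 13.
LIFESPAN_PRESET_CONFIG: dict[str, dict] = {
    "prenatal": {
        "metric": "HC",
        "sex_ratio": 0.526,
        "female_mean": {
            "kind": "piecewise_linear",
            "points": [[11, 6.0], [14, 9.8], [20, 17.5], [25, 23.0],
                       [30, 28.0], [35, 31.9], [40, 34.4]],
        },
        "sd_curve": {
            "kind": "piecewise_linear",
            "points": [[11, 0.45], [20, 0.75], [30, 1.05], [40, 1.3]],
        },
        "trajectory": [[11, 0.30], [20, 0.42], [25, 0.50], [30, 0.40], [40, 0.45]],
    },
    "postnatal": {
        "metric": "HC",
        "sex_ratio": 0.502,
        "female_mean": {
            "kind": "piecewise_linear",
            "points": [[0, 33.9], [3, 39.5], [6, 42.2], [10, 44.2], [12, 44.9],
                       [24, 47.2], [36, 48.6], [60, 50.2], [84, 51.1]],
        },
        "sd_curve": {
            "kind": "piecewise_linear",
            "points": [[0, 1.2], [6, 1.3], [12, 1.35], [24, 1.4], [84, 1.5]],
        },
        "trajectory": [[0, 0.55], [10, 1.10], [24, 0.80], [60, 0.55], [84, 0.50]],
    },
    "mri_cv": {
        "metric": "CV",
        "sex_ratio": 0.52,
        "female_mean": {
            "kind": "logistic",
            "offset": 440_000.0, "scale": 70_000.0, "rate": 0.4, "midpoint": 9.0,
        },
        "sd_curve": {"kind": "constant", "value": 48_000.0},
        "trajectory": [[5, 0.40], [24, 1.40], [43, 1.40], [89, 1.25]],
    },
    "mri_ct": {
        "metric": "CT",
        "sex_ratio": 0.52,
        "female_mean": {
            "kind": "piecewise_linear",
            "points": [[5, 2.72], [10, 2.65], [15, 2.58], [25, 2.50],
                       [50, 2.45], [89, 2.36]],
        },
        "sd_curve": {"kind": "constant", "value": 0.11},
        "trajectory": [[5, -0.25], [13, 0.0], [20, 0.10], [89, 0.10]],
    },
    "mri_icv": {
        "metric": "ICV",
        "sex_ratio": 0.52,
        "female_mean": {
            "kind": "logistic",
            "offset": 1_250_000.0, "scale": 130_000.0, "rate": 0.5, "midpoint": 8.0,
        },
        "sd_curve": {"kind": "constant", "value": 120_000.0},
        "trajectory": [[5, 0.90], [20, 1.15], [89, 1.10]],
    },
}


def lifespan_preset(
    n_mri: int = 25_846,
    dataset_layout: str = "uniform",
) -> dict[str, GrowthModel]:
    """The default lifespan scenario as ready-to-use models.

    ``dataset_layout`` is ``'uniform'`` (one synthetic dataset, uniform
    ages) or ``'study_mix'`` (dataset sizes and age ranges proportional to
    the published MRI roster, giving realistic heterogeneity — e.g. one
    large elderly sample).  The MRI models' ``dataset_sizes`` are scaled to
    ``n_mri`` subjects in total.
    """
    models = {k: model_from_config(v) for k, v in LIFESPAN_PRESET_CONFIG.items()}
    if dataset_layout == "uniform":
        sizes = {"synthetic": int(n_mri)}
    elif dataset_layout == "study_mix":
        sizes, _ = table1_dataset_layout(n_mri)
    else:
        raise ConfigurationError(f"unknown dataset_layout {dataset_layout!r}")
    for key in ("mri_cv", "mri_ct", "mri_icv"):
        models[key] = GrowthModel(
            female_mean=models[key].female_mean,
            sd_curve=models[key].sd_curve,
            trajectory=models[key].trajectory,
            sex_ratio=models[key].sex_ratio,
            dataset_sizes=sizes,
            metric=models[key].metric,
        )
    return models


def table1_dataset_layout(
    n_total: int,
) -> tuple[dict[str, int], dict[str, tuple[float, float]]]:
    """Dataset sizes and age ranges mimicking the published MRI roster.

    Sizes are proportional to the published per-study n (each study gets at
    least one subject); age ranges are the published ones.
    """
    roster = cohorts.MRI_DATASETS
    published_total = cohorts.total_n(roster)
    sizes = {
        s.name: max(1, round(n_total * s.n / published_total)) for s in roster
    }
    ranges = {s.name: (float(s.age_lo), float(s.age_hi)) for s in roster}
    return sizes, ranges
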