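"""Sliding-window effect sizes over individual-level records.

The engine bins cross-sectional subjects into overlapping half-open age
windows of fixed width (default 4 years) advanced by a fixed step (default
2 years), starting at a fixed lower age (default 4 years), computes per-sex
moments inside each window, and evaluates Cohen's d, the mean difference and
the pooled SD at the window centre.  Windows whose total count falls below
``min_n`` (default 60) are flagged low-confidence; windows with fewer than
two subjects of either sex yield an undefined point (an SD needs n ≥ 2).

Width 4 / step 2 balances smoothing against age resolution: with width equal
to twice the step, every subject strictly inside the grid contributes to
exactly two windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effect_size import MomentPair, cohens_d
from .errors import (
    EmptyInputError,
    ParameterError,
    SensitivityUndefinedError,
    UnknownMetricError,
)
from .morphometry_ingest import SubjectRecord

__all__ = [
    "AgeWindow",
    "TrajectoryPoint",
    "METRIC_FIELDS",
    "make_windows",
    "window_membership",
    "windowed_effects",
    "leave_one_dataset_out",
    "DEFAULT_WIDTH",
    "DEFAULT_STEP",
    "DEFAULT_START",
    "DEFAULT_MIN_N",
]

DEFAULT_WIDTH = 4.0
DEFAULT_STEP = 2.0
DEFAULT_START = 4.0
DEFAULT_MIN_N = 60

#: metric name -> SubjectRecord attribute
METRIC_FIELDS: dict[str, str] = {
    "SA": "surface_area",
    "CT": "mean_thickness",
    "CV": "cortical_volume",
    "ICV": "icv",
}


@dataclass(frozen=True)
class AgeWindow:
    """Half-open age bin [lo, hi); membership is lo <= age < hi."""

    lo: float
    hi: float

    @property
    def center(self) -> float:
        return (self.lo + self.hi) / 2.0

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class TrajectoryPoint:
    """One effect-size estimate at one age.

    ``age`` is the window centre for windowed estimates, or the chart epoch
    (gestational week / postnatal month) for chart-derived points.  When
    ``defined`` is False the statistics are absent (None).
    """

    age: float
    tier: str  # 'prenatal' | 'postnatal' | 'mri'
    metric: str  # 'HC' | 'SA' | 'CT' | 'CV' | 'ICV'
    d: float | None = None
    mean_diff: float | None = None
    pooled_sd: float | None = None
    n_m: int = 0
    n_f: int = 0
    low_confidence: bool = False
    defined: bool = True
    source: str = ""


def make_windows(
    min_age: float,
    max_age: float,
    width: float = DEFAULT_WIDTH,
    step: float = DEFAULT_STEP,
) -> list[AgeWindow]:
    """Sliding-window grid: [min_age + k·step, min_age + k·step + width).

    Windows are generated while the window start is strictly below
    ``max_age``, so trailing windows may extend past the oldest subject
    (they simply come back undefined or low-confidence downstream).
    """
    if width <= 0 or step <= 0:
        raise ParameterError(f"width and step must be > 0, got ({width}, {step})")
    windows = []
    k = 0
    while True:
        lo = min_age + k * step
        if not lo < max_age:
            break
        windows.append(AgeWindow(lo=lo, hi=lo + width))
        k += 1
    return windows


def window_membership(record_age: float, window: AgeWindow) -> bool:
    """Half-open membership test: lo <= age < hi."""
    return window.lo <= record_age < window.hi


def _metric_arrays(
    records: Sequence[SubjectRecord], metric: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (age, is_male, value) arrays, dropping records lacking the metric."""
    try:
        attr = METRIC_FIELDS[metric]
    except KeyError:
        raise UnknownMetricError(
            f"unknown metric {metric!r}; expected one of {sorted(METRIC_FIELDS)}"
        ) from None
    ages, male, values = [], [], []
    for r in records:
        v = getattr(r, attr)
        if v is None:
            continue
        ages.append(r.age)
        male.append(r.sex == "M")
        values.append(v)
    return np.asarray(ages, float), np.asarray(male, bool), np.asarray(values, float)


def windowed_effects(
    records: Sequence[SubjectRecord],
    metric: str,
    width: float = DEFAULT_WIDTH,
    step: float = DEFAULT_STEP,
    min_n: int = DEFAULT_MIN_N,
    start: float = DEFAULT_START,
    windows: Sequence[AgeWindow] | None = None,
    tier: str = "mri",
    source: str = "",
) -> list[TrajectoryPoint]:
    """Sliding-window Cohen's d trajectory over individual-level records.

    For each window, subjects with ``start <= age < hi`` belonging to the
    half-open bin are split by sex; per-sex mean and SD (ddof=1) feed the
    pooled-SD Cohen's d.  A window needs at least two subjects of each sex
    to be defined; a defined window with total n below ``min_n`` is flagged
    ``low_confidence``.  The point's age is the window centre.

    ``windows`` overrides the automatic grid (used e.g. to keep a fixed
    grid across leave-one-dataset-out reruns).
    """
    if len(records) == 0:
        raise EmptyInputError("no records supplied")
    ages, male, values = _metric_arrays(records, metric)
    if ages.size == 0:
        raise EmptyInputError(f"no records carry metric {metric!r}")
    if windows is None:
        windows = make_windows(start, float(ages.max()), width=width, step=step)

    points: list[TrajectoryPoint] = []
    for w in windows:
        mask = (ages >= w.lo) & (ages < w.hi)
        m_vals = values[mask & male]
        f_vals = values[mask & ~male]
        n_m, n_f = m_vals.size, f_vals.size
        low_conf = (n_m + n_f) < min_n
        if n_m < 2 or n_f < 2:
            points.append(
                TrajectoryPoint(
                    age=w.center, tier=tier, metric=metric, n_m=n_m, n_f=n_f,
                    low_confidence=low_conf, defined=False, source=source,
                )
            )
            continue
        sd_m = float(np.std(m_vals, ddof=1))
        sd_f = float(np.std(f_vals, ddof=1))
        if sd_m == 0.0 and sd_f == 0.0:
            points.append(
                TrajectoryPoint(
                    age=w.center, tier=tier, metric=metric, n_m=n_m, n_f=n_f,
                    low_confidence=low_conf, defined=False, source=source,
                )
            )
            continue
        res = cohens_d(
            MomentPair(
                mean_m=float(np.mean(m_vals)),
                mean_f=float(np.mean(f_vals)),
                sd_m=sd_m,
                sd_f=sd_f,
                n_m=n_m,
                n_f=n_f,
            )
        )
        points.append(
            TrajectoryPoint(
                age=w.center, tier=tier, metric=metric,
                d=res.d, mean_diff=res.mean_diff, pooled_sd=res.pooled_sd,
                n_m=n_m, n_f=n_f, low_confidence=low_conf, defined=True,
                source=source,
            )
        )
    return points


def leave_one_dataset_out(
    records: Sequence[SubjectRecord],
    metric: str,
    width: float = DEFAULT_WIDTH,
    step: float = DEFAULT_STEP,
    min_n: int = DEFAULT_MIN_N,
    start: float = DEFAULT_START,
) -> dict[str, list[TrajectoryPoint]]:
    """Sensitivity analysis: recompute the trajectory with each dataset removed.

    The window grid is fixed to the full-data grid, so every leave-one-out
    trajectory is comparable point-by-point with the full trajectory (ages
    beyond the remaining data simply come back undefined).
    """
    dataset_ids = sorted({r.dataset_id for r in records})
    if len(dataset_ids) < 2:
        raise SensitivityUndefinedError(
            f"need >= 2 distinct datasets, got {dataset_ids}"
        )
    ages, _, _ = _metric_arrays(records, metric)
    if ages.size == 0:
        raise EmptyInputError(f"no records carry metric {metric!r}")
    grid = make_windows(start, float(ages.max()), width=width, step=step)
    out: dict[str, list[TrajectoryPoint]] = {}
    for ds in dataset_ids:
        subset = [r for r in records if r.dataset_id != ds]
        out[ds] = windowed_effects(
            subset, metric, width=width, step=step, min_n=min_n,
            start=start, windows=grid, source=f"loo:{ds}",
        )
    return out
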