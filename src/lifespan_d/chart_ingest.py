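"""Extract per-age moments and effect trajectories from growth-chart sources.

Published growth references come in two summary dialects:

1. Centile-chart tables — per age epoch (gestational week or postnatal
   month) and sex, a 50th-percentile value, usually with an SD, sometimes
   with only outer centiles.  Under a normality assumption the P50 is taken
   as the mean, and when only outer centiles are published the SD is
   back-calculated from their span.
2. Regression models — per sex, polynomial equations giving mean(age) and
   SD(age) over a stated valid age range.

Either dialect yields per-epoch male/female :class:`MomentPair` values and
hence a Cohen's d trajectory.  Epochs are matched exactly across sexes (all
published references tabulate both sexes on the same grid); an epoch present
in only one sex is skipped with a log message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial import Polynomial
from scipy.stats import norm

from .effect_size import MomentPair, cohens_d
from .errors import (
    DomainError,
    EmptyInputError,
    ExtrapolationError,
    InvalidSpecError,
    UnsupportedDialectError,
    UnusableRowError,
)
from .window_engine import TrajectoryPoint

__all__ = [
    "ChartRow",
    "RegressionSpec",
    "moments_from_chart_row",
    "sd_from_percentile_span",
    "moments_from_regression",
    "chart_effect_trajectory",
    "regression_effect_trajectory",
    "read_chart_csv",
    "write_chart_csv",
    "load_regression_specs",
    "CHART_COLUMNS",
]

log = logging.getLogger(__name__)

#: long-format chart CSV schema (one file per source, one row per sex x epoch)
CHART_COLUMNS = [
    "source", "tier", "age", "age_unit", "sex",
    "p50", "sd", "p_lo", "rank_lo", "p_hi", "rank_hi",
]


@dataclass(frozen=True)
class ChartRow:
    """One sex's published summary at one age epoch."""

    age: float  # gestational week or postnatal month
    sex: str  # 'M' or 'F'
    p50: float | None = None
    sd: float | None = None
    p_lo: float | None = None
    rank_lo: float | None = None  # nominal percentile rank of p_lo (e.g. 3)
    p_hi: float | None = None
    rank_hi: float | None = None
    source: str = ""
    tier: str = "postnatal"  # 'prenatal' | 'postnatal'
    age_unit: str = "month"  # 'week' | 'month'

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DomainError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("M", "F"):
            raise DomainError(f"sex must be 'M' or 'F', got {self.sex!r}")


def sd_from_percentile_span(
    p_lo: float, p_hi: float, rank_lo: float, rank_hi: float
) -> float:
    """Back-calculate a normal SD from two symmetric outer centiles.

    Under normality, SD = (p_hi − p_lo) / (z(rank_hi/100) − z(rank_lo/100)).
    The ranks must be symmetric about the median (rank_lo + rank_hi = 100);
    asymmetric layouts would require a skewed model and are rejected.
    """
    if not np.isclose(rank_lo + rank_hi, 100.0):
        raise UnsupportedDialectError(
            f"percentile ranks must be symmetric about 50, got ({rank_lo}, {rank_hi})"
        )
    if not 0 < rank_lo < rank_hi < 100:
        raise DomainError(f"ranks must satisfy 0 < lo < hi < 100, got ({rank_lo}, {rank_hi})")
    if p_hi <= p_lo:
        raise DomainError(f"p_hi must exceed p_lo, got ({p_lo}, {p_hi})")
    z_span = norm.ppf(rank_hi / 100.0) - norm.ppf(rank_lo / 100.0)
    return (p_hi - p_lo) / z_span


def moments_from_chart_row(row: ChartRow) -> tuple[float, float]:
    """(mean, SD) from one chart row: mean := P50; SD direct or from centiles."""
    if row.p50 is None:
        raise UnusableRowError(f"row at age {row.age} ({row.sex}) lacks a P50 value")
    if row.sd is not None:
        if row.sd < 0:
            raise DomainError(f"SD must be >= 0, got {row.sd}")
        return row.p50, row.sd
    if row.p_lo is not None and row.p_hi is not None:
        if row.rank_lo is None or row.rank_hi is None:
            raise UnusableRowError(
                f"row at age {row.age} ({row.sex}) has centiles without ranks"
            )
        return row.p50, sd_from_percentile_span(row.p_lo, row.p_hi, row.rank_lo, row.rank_hi)
    raise UnusableRowError(
        f"row at age {row.age} ({row.sex}) offers no SD route (no sd, no outer centiles)"
    )


@dataclass(frozen=True)
class RegressionSpec:
    """Sex-specific polynomial model of mean(age) and SD(age).

    Coefficients are in ascending order (c0 + c1·age + c2·age² + ...).
    The SD polynomial must be strictly positive over ``valid_age_range``.
    """

    sex: str
    mean_coeffs: tuple[float, ...]
    sd_coeffs: tuple[float, ...]
    valid_age_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise DomainError(f"sex must be 'M' or 'F', got {self.sex!r}")
        lo, hi = self.valid_age_range
        if not lo < hi:
            raise InvalidSpecError(f"valid_age_range must have lo < hi, got ({lo}, {hi})")
        grid = np.linspace(lo, hi, 257)
        if np.any(Polynomial(self.sd_coeffs)(grid) <= 0):
            raise InvalidSpecError(
                f"SD polynomial is not strictly positive on [{lo}, {hi}]"
            )

    def mean(self, age: float) -> float:
        self._check_age(age)
        return float(Polynomial(self.mean_coeffs)(age))

    def sd(self, age: float) -> float:
        self._check_age(age)
        return float(Polynomial(self.sd_coeffs)(age))

    def _check_age(self, age: float) -> None:
        lo, hi = self.valid_age_range
        if not lo <= age <= hi:
            raise ExtrapolationError(
                f"age {age} outside valid range [{lo}, {hi}] for sex {self.sex}"
            )


def moments_from_regression(
    spec_m: RegressionSpec, spec_f: RegressionSpec, age: float
) -> MomentPair:
    """Evaluate both sexes' regression models at one epoch."""
    if spec_m.sex != "M" or spec_f.sex != "F":
        raise InvalidSpecError("spec_m must have sex 'M' and spec_f sex 'F'")
    sd_m, sd_f = spec_m.sd(age), spec_f.sd(age)
    if sd_m <= 0 or sd_f <= 0:
        raise InvalidSpecError(f"SD regression evaluates <= 0 at age {age}")
    return MomentPair(
        mean_m=spec_m.mean(age), mean_f=spec_f.mean(age), sd_m=sd_m, sd_f=sd_f
    )


def chart_effect_trajectory(
    rows_m: Sequence[ChartRow], rows_f: Sequence[ChartRow]
) -> list[TrajectoryPoint]:
    """Per-epoch Cohen's d trajectory from matched male/female chart rows.

    Epochs are matched by exact age value; epochs present in only one sex
    are skipped (logged).  Output is sorted by age, one point per matched
    epoch, with counts unknown (0).
    """
    by_age_m = _index_rows(rows_m, "M")
    by_age_f = _index_rows(rows_f, "F")
    common = sorted(set(by_age_m) & set(by_age_f))
    for age in sorted(set(by_age_m) ^ set(by_age_f)):
        side = "female" if age in by_age_m else "male"
        log.info("epoch %s present in one sex only (missing %s row); skipped", age, side)
    points: list[TrajectoryPoint] = []
    for age in common:
        row_m, row_f = by_age_m[age], by_age_f[age]
        mean_m, sd_m = moments_from_chart_row(row_m)
        mean_f, sd_f = moments_from_chart_row(row_f)
        res = cohens_d(MomentPair(mean_m=mean_m, mean_f=mean_f, sd_m=sd_m, sd_f=sd_f))
        points.append(
            TrajectoryPoint(
                age=age, tier=row_m.tier, metric="HC",
                d=res.d, mean_diff=res.mean_diff, pooled_sd=res.pooled_sd,
                source=row_m.source,
            )
        )
    if not points:
        raise EmptyInputError("no epochs are present in both sexes")
    return points


def regression_effect_trajectory(
    spec_m: RegressionSpec,
    spec_f: RegressionSpec,
    ages: Sequence[float],
    tier: str = "prenatal",
    source: str = "",
) -> list[TrajectoryPoint]:
    """Cohen's d trajectory evaluated from regression models on an age grid."""
    points = []
    for age in sorted(ages):
        res = cohens_d(moments_from_regression(spec_m, spec_f, age))
        points.append(
            TrajectoryPoint(
                age=float(age), tier=tier, metric="HC",
                d=res.d, mean_diff=res.mean_diff, pooled_sd=res.pooled_sd,
                source=source,
            )
        )
    if not points:
        raise EmptyInputError("no evaluation ages supplied")
    return points


def _index_rows(rows: Sequence[ChartRow], sex: str) -> dict[float, ChartRow]:
    out: dict[float, ChartRow] = {}
    for row in rows:
        if row.sex != sex:
            raise DomainError(f"expected sex {sex!r} rows, got {row.sex!r} at age {row.age}")
        if row.age in out:
            raise DomainError(f"duplicate epoch {row.age} for sex {sex}")
        out[row.age] = row
    return out


def read_chart_csv(path: str | Path) -> dict[str, list[ChartRow]]:
    """Read a long-format chart CSV into rows keyed by sex ('M'/'F').

    Schema: ``source,tier,age,age_unit,sex,p50,sd,p_lo,rank_lo,p_hi,rank_hi``
    with empty cells for missing values.
    """
    df = pd.read_csv(path)
    missing = [c for c in CHART_COLUMNS if c not in df.columns]
    if missing:
        raise UnusableRowError(f"chart file {path} missing column(s) {missing}")

    def opt(v) -> float | None:
        return None if pd.isna(v) else float(v)

    out: dict[str, list[ChartRow]] = {"M": [], "F": []}
    for _, r in df.iterrows():
        row = ChartRow(
            age=float(r["age"]), sex=str(r["sex"]),
            p50=opt(r["p50"]), sd=opt(r["sd"]),
            p_lo=opt(r["p_lo"]), rank_lo=opt(r["rank_lo"]),
            p_hi=opt(r["p_hi"]), rank_hi=opt(r["rank_hi"]),
            source=str(r["source"]), tier=str(r["tier"]), age_unit=str(r["age_unit"]),
        )
        out[row.sex].append(row)
    return out


def write_chart_csv(rows: Sequence[ChartRow], path: str | Path) -> None:
    """Write chart rows in the long-format schema (empty cells for None)."""
    df = pd.DataFrame(
        [
            {
                "source": r.source, "tier": r.tier, "age": r.age,
                "age_unit": r.age_unit, "sex": r.sex, "p50": r.p50, "sd": r.sd,
                "p_lo": r.p_lo, "rank_lo": r.rank_lo, "p_hi": r.p_hi,
                "rank_hi": r.rank_hi,
            }
            for r in rows
        ],
        columns=CHART_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_regression_specs(path: str | Path) -> tuple[RegressionSpec, RegressionSpec]:
    """Load a (male, female) regression-spec pair from a YAML document.

    Expected layout::

        valid_age_range: [15, 40]
        M: {mean_coeffs: [...], sd_coeffs: [...]}
        F: {mean_coeffs: [...], sd_coeffs: [...]}

    A per-sex ``valid_age_range`` overrides the top-level one.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = {}
    for sex in ("M", "F"):
        if sex not in doc:
            raise InvalidSpecError(f"regression document {path} lacks a {sex!r} section")
        sec = doc[sex]
        rng = sec.get("valid_age_range", doc.get("valid_age_range"))
        if rng is None:
            raise InvalidSpecError(f"no valid_age_range for sex {sex} in {path}")
        specs[sex] = RegressionSpec(
            sex=sex,
            mean_coeffs=tuple(float(c) for c in sec["mean_coeffs"]),
            sd_coeffs=tuple(float(c) for c in sec["sd_coeffs"]),
            valid_age_range=(float(rng[0]), float(rng[1])),
        )
    return specs["M"], specs["F"]
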