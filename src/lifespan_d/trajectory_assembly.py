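"""Harmonize trajectories from all tiers onto one lifespan axis and render figures.

The three tiers report ages in incompatible units — gestational weeks
(prenatal ultrasound charts), postnatal months (growth references), and
years (windowed morphometry).  For a single lifespan figure they are mapped
onto post-conception days with a fixed 280-day term, so the prenatal /
postnatal junction is exact (gestational week 40 and postnatal month 0 land
on the same abscissa) and a logarithmic axis is meaningful from mid-gestation
to old age.

Conversions (deterministic by construction):

    prenatal:   days = weeks × 7
    postnatal:  days = 280 + months × 365.25/12
    mri:        days = 280 + years × 365.25
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import DomainError, EmptyInputError
from .window_engine import TrajectoryPoint

__all__ = [
    "LifespanSeries",
    "to_common_axis",
    "combine",
    "write_tidy",
    "read_tidy",
    "render_figures",
    "TIDY_COLUMNS",
    "TERM_DAYS",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "AGE_UNITS",
]

log = logging.getLogger(__name__)

TERM_DAYS = 280.0  # full-term gestation, post-conception days
DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25

AGE_UNITS = {"prenatal": "week", "postnatal": "month", "mri": "year"}

TIDY_COLUMNS = [
    "source", "tier", "metric", "age", "age_unit", "axis_days",
    "d", "mean_diff", "pooled_sd", "n_m", "n_f", "low_confidence", "defined",
]

#: default demarcated ages (years post-birth) for the combined log-axis figure
DEFAULT_TICK_YEARS = [0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 90.0]


def to_common_axis(age: float, tier: str) -> float:
    """Map a tier-native age onto post-conception days."""
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    if tier == "prenatal":
        return age * 7.0
    if tier == "postnatal":
        return TERM_DAYS + age * DAYS_PER_MONTH
    if tier == "mri":
        return TERM_DAYS + age * DAYS_PER_YEAR
    raise DomainError(f"unknown tier {tier!r}")


@dataclass
class LifespanSeries:
    """Trajectory points with their common post-conception-day abscissae."""

    points: list[TrajectoryPoint] = field(default_factory=list)

    @property
    def axis(self) -> list[float]:
        return [to_common_axis(p.age, p.tier) for p in self.points]

    def groups(self) -> dict[tuple[str, str, str], list[TrajectoryPoint]]:
        """Points grouped by (tier, metric, source), each group axis-sorted."""
        out: dict[tuple[str, str, str], list[TrajectoryPoint]] = {}
        for p in self.points:
            out.setdefault((p.tier, p.metric, p.source), []).append(p)
        for key, pts in out.items():
            pts.sort(key=lambda p: to_common_axis(p.age, p.tier))
        return out

    def __len__(self) -> int:
        return len(self.points)


def combine(series: Sequence[LifespanSeries]) -> LifespanSeries:
    """Concatenate series, grouped by (tier, metric, source) and axis-sorted.

    No point is altered and no cross-tier interpolation or averaging is
    performed; the result is permutation-invariant in its inputs.
    """
    pts: list[TrajectoryPoint] = []
    for s in series:
        pts.extend(s.points)
    if not pts:
        raise EmptyInputError("all input series are empty")
    merged = LifespanSeries(points=pts)
    ordered: list[TrajectoryPoint] = []
    for key in sorted(merged.groups()):
        ordered.extend(merged.groups()[key])
    return LifespanSeries(points=ordered)


def write_tidy(series: LifespanSeries, path: str | Path) -> None:
    """Write one row per point in the tidy schema.

    Floats are formatted with 9 significant digits for byte-stable reruns.
    """
    rows = []
    for p in series.points:
        rows.append(
            {
                "source": p.source,
                "tier": p.tier,
                "metric": p.metric,
                "age": _fmt(p.age),
                "age_unit": AGE_UNITS[p.tier],
                "axis_days": _fmt(to_common_axis(p.age, p.tier)),
                "d": _fmt(p.d),
                "mean_diff": _fmt(p.mean_diff),
                "pooled_sd": _fmt(p.pooled_sd),
                "n_m": p.n_m,
                "n_f": p.n_f,
                "low_confidence": p.low_confidence,
                "defined": p.defined,
            }
        )
    pd.DataFrame(rows, columns=TIDY_COLUMNS).to_csv(path, index=False)


def _fmt(x: float | None) -> str:
    return "" if x is None else format(float(x), ".9g")


def read_tidy(path: str | Path) -> LifespanSeries:
    """Read a tidy trajectory CSV back into a series."""
    df = pd.read_csv(path)
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise EmptyInputError(f"tidy file {path} missing column(s) {missing}")
    points = []
    for _, r in df.iterrows():
        points.append(
            TrajectoryPoint(
                age=float(r["age"]),
                tier=str(r["tier"]),
                metric=str(r["metric"]),
                d=None if pd.isna(r["d"]) else float(r["d"]),
                mean_diff=None if pd.isna(r["mean_diff"]) else float(r["mean_diff"]),
                pooled_sd=None if pd.isna(r["pooled_sd"]) else float(r["pooled_sd"]),
                n_m=int(r["n_m"]),
                n_f=int(r["n_f"]),
                low_confidence=bool(r["low_confidence"]),
                defined=bool(r["defined"]),
                source="" if pd.isna(r["source"]) else str(r["source"]),
            )
        )
    return LifespanSeries(points=points)


def render_figures(
    series: LifespanSeries,
    outdir: str | Path,
    tick_years: Sequence[float] = DEFAULT_TICK_YEARS,
    fmt: str = "png",
) -> list[Path]:
    """Render per-tier triptychs and the combined log-axis lifespan figure.

    Per (tier, source, metric) group, a three-panel figure shows d, mean
    difference and pooled SD against native age.  The combined figure shows
    every group's d against log post-conception days with demarcated ages.
    Undefined points are omitted; low-confidence points are drawn hollow.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    groups = series.groups()

    for (tier, metric, source), pts in groups.items():
        defined = [p for p in pts if p.defined]
        if not defined:
            log.info("group %s has no defined points; skipped", (tier, metric, source))
            continue
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.4), constrained_layout=True)
        unit = AGE_UNITS[tier]
        for ax, attr, label in zip(
            axes,
            ("d", "mean_diff", "pooled_sd"),
            ("Cohen's d (M vs F)", "mean difference", "pooled SD"),
        ):
            _scatter_confidence(ax, defined, attr, x=lambda p: p.age)
            ax.set_xlabel(f"age ({unit})")
            ax.set_ylabel(label)
            if attr == "d":
                ax.axhline(0.0, lw=0.6, color="0.6")
        title = " / ".join(x for x in (tier, metric, source) if x)
        fig.suptitle(title)
        name = "_".join(x for x in (tier, metric, source) if x)
        path = outdir / f"trajectory_{_safe(name)}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    # combined lifespan figure, log post-conception days
    fig, ax = plt.subplots(figsize=(8, 4.5), constrained_layout=True)
    any_points = False
    for (tier, metric, source), pts in groups.items():
        defined = [p for p in pts if p.defined]
        if not defined:
            continue
        any_points = True
        xs = [to_common_axis(p.age, p.tier) for p in defined]
        ys = [p.d for p in defined]
        label = " ".join(x for x in (tier, metric, source) if x)
        (line,) = ax.plot(xs, ys, lw=1.0, label=label)
        lo_x = [x for x, p in zip(xs, defined) if p.low_confidence]
        lo_y = [p.d for p in defined if p.low_confidence]
        hi_x = [x for x, p in zip(xs, defined) if not p.low_confidence]
        hi_y = [p.d for p in defined if not p.low_confidence]
        ax.plot(hi_x, hi_y, "o", ms=2.5, color=line.get_color())
        if lo_x:
            ax.plot(lo_x, lo_y, "o", ms=3.5, mfc="none", color=line.get_color(),
                    label=f"{label} (low confidence)")
    if any_points:
        ax.set_xscale("log")
        ticks = [TERM_DAYS + y * DAYS_PER_YEAR for y in tick_years]
        ax.set_xticks(ticks)
        ax.set_xticklabels(
            ["birth" if y == 0 else f"{y:g} y" for y in tick_years]
        )
        ax.axhline(0.0, lw=0.6, color="0.6")
        ax.set_xlabel("age (post-conception days, log scale)")
        ax.set_ylabel("Cohen's d (M vs F)")
        ax.legend(fontsize=6, loc="best")
        path = outdir / f"lifespan_combined.{fmt}"
        fig.savefig(path, dpi=150)
        written.append(path)
    plt.close(fig)
    return written


def _scatter_confidence(ax, points, attr, x):
    hi = [p for p in points if not p.low_confidence]
    lo = [p for p in points if p.low_confidence]
    if hi:
        ax.plot([x(p) for p in hi], [getattr(p, attr) for p in hi], "o-", ms=3, lw=0.8)
    if lo:
        ax.plot(
            [x(p) for p in lo], [getattr(p, attr) for p in lo],
            "o", ms=4, mfc="none", label="low confidence",
        )
        ax.legend(fontsize=6)


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "-" for c in name)
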