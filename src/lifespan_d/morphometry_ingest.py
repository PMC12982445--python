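"""Ingest individual-level cortical morphometry tables.

Input is a delimited text export of per-subject global morphometry summaries
(one row per scan) of the kind produced by surface-reconstruction pipelines:
total cortical surface area (mm²), mean cortical thickness (mm), and
optionally intracranial volume (mm³).  Cortical volume is derived per
subject as the product of total surface area and mean thickness — preferred
over ICV because the skull stabilises in early adolescence while the cortex
keeps changing.

Column names and sex codes vary across source datasets, so the reader takes
a column map and a sex-code map.  Rows violating basic invariants (negative
age, non-positive area or thickness, undecodable sex) are dropped and
counted in a rejection report so that record count + rejection count always
equals the input row count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DomainError, EmptyInputError, SchemaError

__all__ = [
    "SubjectRecord",
    "RejectionReport",
    "cortical_volume",
    "read_subject_table",
    "write_subject_table",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_SEX_CODES",
]

#: canonical column-map keys -> default column names in the input table
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "subject": "subject_id",
    "dataset": "dataset_id",
    "sex": "sex",
    "age": "age",
    "surf_area": "surface_area",
    "mean_thickness": "mean_thickness",
    "icv": "icv",
    "visit": "visit",
}

DEFAULT_SEX_CODES: dict[str, str] = {"M": "M", "F": "F", "m": "M", "f": "F"}

_REQUIRED_KEYS = ("subject", "dataset", "sex", "age", "surf_area", "mean_thickness")


@dataclass(frozen=True)
class SubjectRecord:
    """One individual's global morphometry at one (baseline) timepoint."""

    subject_id: str
    dataset_id: str
    sex: str  # 'M' or 'F'
    age: float  # years
    surface_area: float  # mm^2
    mean_thickness: float  # mm
    icv: float | None = None  # mm^3, optional
    cortical_volume: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise DomainError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age < 0:
            raise DomainError(f"age must be >= 0, got {self.age}")
        object.__setattr__(
            self, "cortical_volume", cortical_volume(self.surface_area, self.mean_thickness)
        )


@dataclass
class RejectionReport:
    """Bookkeeping for rows dropped at ingest, keyed by reason."""

    n_input: int = 0
    n_kept: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return sum(self.reasons.values())


def cortical_volume(surface_area: float, mean_thickness: float) -> float:
    """Per-subject cortical volume (mm³) = total surface area × mean thickness."""
    if surface_area <= 0 or mean_thickness <= 0:
        raise DomainError(
            "surface area and mean thickness must be > 0, got "
            f"({surface_area}, {mean_thickness})"
        )
    return surface_area * mean_thickness


def read_subject_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sex_codes: Mapping[object, str] | None = None,
) -> tuple[list[SubjectRecord], RejectionReport]:
    """Read a per-subject morphometry table into validated records.

    Parameters
    ----------
    path
        Delimited text file (comma or tab, autodetected), header required.
    column_map
        Maps canonical keys ``subject, dataset, sex, age, surf_area,
        mean_thickness, icv, visit`` to column names in the file.  ``icv``
        and ``visit`` are optional; the rest are required.  Defaults to
        :data:`DEFAULT_COLUMN_MAP`.
    sex_codes
        Maps the file's sex vocabulary to 'M'/'F' (e.g. ``{1: 'M', 2: 'F'}``).

    Returns
    -------
    (records, report)
        Validated records (ages in years, cortical volume populated) and a
        :class:`RejectionReport`.  When a ``visit`` column is mapped, only
        each subject's earliest-age row is kept (baseline-only rule);
        later visits are counted as rejections with reason ``'non_baseline'``.

    Raises
    ------
    SchemaError
        If a required mapped column is absent.
    EmptyInputError
        If no row survives validation.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    codes = dict(DEFAULT_SEX_CODES) if sex_codes is None else dict(sex_codes)
    # accept both raw and stringified keys (CSV cells read as strings/ints)
    str_codes = {str(k): v for k, v in codes.items()}

    df = pd.read_csv(path, sep=None, engine="python")
    missing = [cmap[k] for k in _REQUIRED_KEYS if cmap[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    has_icv = "icv" in cmap and cmap["icv"] in df.columns
    has_visit = "visit" in cmap and cmap["visit"] in df.columns

    report = RejectionReport(n_input=len(df))
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        try:
            raw_sex = row[cmap["sex"]]
            sex = str_codes.get(str(raw_sex))
            if sex is None:
                raise DomainError(f"undecodable sex code {raw_sex!r}")
            icv = None
            if has_icv and pd.notna(row[cmap["icv"]]):
                icv = float(row[cmap["icv"]])
                if icv <= 0:
                    raise DomainError(f"icv must be > 0, got {icv}")
            rec = SubjectRecord(
                subject_id=str(row[cmap["subject"]]),
                dataset_id=str(row[cmap["dataset"]]),
                sex=sex,
                age=float(row[cmap["age"]]),
                surface_area=float(row[cmap["surf_area"]]),
                mean_thickness=float(row[cmap["mean_thickness"]]),
                icv=icv,
            )
        except (DomainError, ValueError, TypeError) as exc:
            report.reasons["invalid_row"] += 1
            continue
        records.append(rec)

    if has_visit:
        records, n_dropped = _baseline_only(records)
        report.reasons["non_baseline"] += n_dropped

    report.n_kept = len(records)
    if not records:
        raise EmptyInputError(f"no valid subject rows in {path}")
    return records, report


def _baseline_only(records: list[SubjectRecord]) -> tuple[list[SubjectRecord], int]:
    """Keep only the earliest-age record per subject id."""
    best: dict[str, SubjectRecord] = {}
    for rec in records:
        cur = best.get(rec.subject_id)
        if cur is None or rec.age < cur.age:
            best[rec.subject_id] = rec
    kept = [r for r in records if best[r.subject_id] is r]
    return kept, len(records) - len(kept)


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    """Serialise records to CSV using the canonical default column names."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "dataset_id": [r.dataset_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "surface_area": [r.surface_area for r in records],
            "mean_thickness": [r.mean_thickness for r in records],
            "icv": [r.icv for r in records],
        }
    )
    df.to_csv(path, index=False)
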