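"""Published per-study sample rosters for the three lifespan tiers.

These are the printed demographics of the source cohorts the pipeline was
designed around: four prenatal ultrasound studies (head circumference by
gestational week), three postnatal growth-reference surveys (head
circumference by month), and 33 structural-MRI samples (ages 5–89 years).
They serve two purposes: documenting the scale of data each tier expects,
and parameterising the dataset-heterogeneity preset of the synthetic
generator (unequal sample sizes, study-specific age ranges, near-parity
sex ratios).

Sex ratios are male/female; a ratio of 0 marks a female-only sample.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StudyRoster",
    "PRENATAL_STUDIES",
    "POSTNATAL_STUDIES",
    "MRI_DATASETS",
    "total_n",
    "cohort_totals",
]


@dataclass(frozen=True)
class StudyRoster:
    """One contributing study: its size, age coverage, and sex ratio."""

    name: str
    n: int
    age_lo: float  # in the tier's native unit (weeks / months / years)
    age_hi: float
    mf_ratio: float | None = None  # male/female; None = not reported


#: Prenatal ultrasound studies (ages in gestational weeks).
PRENATAL_STUDIES: tuple[StudyRoster, ...] = (
    StudyRoster("Galjaard 2019 (GAMLSS centiles)", 9_413, 12, 40, 1.09),
    StudyRoster("Schwarzler 2004 (regression model)", 12_132, 15, 42, 1.15),
    StudyRoster("Snijders 1994 (centile chart)", 5_055, 15, 40, 1.05),
    StudyRoster("Yazdi 2014 (centile chart)", 1_955, 11, 39, 1.11),
)

#: Postnatal growth-reference surveys (ages in months).
POSTNATAL_STUDIES: tuple[StudyRoster, ...] = (
    StudyRoster("WHO MGRS", 8_406, 0, 71, 1.07),
    StudyRoster("CDC 2000 growth charts", 7_432, 0, 60, 1.05),
    StudyRoster("NSPGDC-4", 69_760, 0, 84, 1.00),
)

#: Structural-MRI samples (ages in years).
MRI_DATASETS: tuple[StudyRoster, ...] = (
    StudyRoster("ABCD", 3_759, 8, 11, 0.90),
    StudyRoster("ABIDE I", 438, 6, 21, 4.28),
    StudyRoster("ABIDE II", 433, 5, 21, 2.07),
    StudyRoster("ADHD-200", 389, 7, 21, 0.87),
    StudyRoster("Ann Arbor a", 24, 13, 41, 7.00),
    StudyRoster("Ann Arbor b", 33, 19, 80, 0.83),
    StudyRoster("Atlanta", 28, 22, 57, 0.87),
    StudyRoster("Baltimore", 23, 20, 40, 0.53),
    StudyRoster("Bangor", 20, 19, 38, 0.0),
    StudyRoster("Beijing Zang", 198, 18, 26, 0.62),
    StudyRoster("Berlin Marguiles", 26, 23, 44, 1.00),
    StudyRoster("Cam-CAN", 643, 18, 89, 0.95),
    StudyRoster("Cambridge", 198, 18, 30, 0.61),
    StudyRoster("HCP aging", 1_838, 36, 89, 0.82),
    StudyRoster("HCP development", 652, 5, 22, 0.86),
    StudyRoster("Healthy brain network/CMI", 214, 5, 21, 1.23),
    StudyRoster("ICBM", 85, 19, 85, 0.89),
    StudyRoster("Imagen", 1_840, 13, 16, 0.96),
    StudyRoster("Leiden_2180", 12, 20, 27, 0.0),
    StudyRoster("Leiden_2200", 19, 18, 28, 1.38),
    StudyRoster("Milwaukee_b", 46, 44, 65, 0.48),
    StudyRoster("Munchen", 16, 63, 74, 1.67),
    StudyRoster("Newark", 19, 21, 39, 0.67),
    StudyRoster("New York_b", 20, 18, 46, 0.67),
    StudyRoster("NYU_TRT", 25, 22, 49, 0.90),
    StudyRoster("Orangeburg", 20, 25, 55, 3.00),
    StudyRoster("Oulu", 103, 20, 23, 0.56),
    StudyRoster("Oxford", 22, 20, 35, 1.20),
    StudyRoster("Palo Alto", 17, 23, 39, 0.13),
    StudyRoster("Queensland", 19, 23, 34, 1.38),
    StudyRoster("Rockland", 140, 6, 21, 1.22),
    StudyRoster("Saint Louis", 31, 21, 29, 0.50),
    StudyRoster("UK Biobank", 14_496, 45, 82, 1.23),
)


def total_n(studies: tuple[StudyRoster, ...]) -> int:
    """Sum of per-study sample sizes."""
    return sum(s.n for s in studies)


def cohort_totals() -> dict[str, int]:
    """Per-tier and grand-total sample sizes across all rosters."""
    pre = total_n(PRENATAL_STUDIES)
    post = total_n(POSTNATAL_STUDIES)
    mri = total_n(MRI_DATASETS)
    return {
        "prenatal": pre,
        "postnatal": post,
        "mri": mri,
        "total": pre + post + mri,
    }
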