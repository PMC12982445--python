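import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lifespan_d.morphometry_ingest import SubjectRecord  # noqa: E402


def random_records(
    n: int,
    seed: int,
    age_range: tuple[float, float] = (5.0, 89.0),
    n_datasets: int = 3,
) -> list[SubjectRecord]:
    """Unstructured random cohort used by oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"s{i:05d}",
                dataset_id=f"ds{rng.integers(n_datasets)}",
                sex="M" if rng.random() < 0.5 else "F",
                age=float(rng.uniform(*age_range)),
                surface_area=float(rng.normal(180_000, 18_000)),
                mean_thickness=float(rng.normal(2.5, 0.12)),
                icv=float(rng.normal(1_400_000, 130_000)),
            )
        )
    return records


@pytest.fixture
def small_cohort() -> list[SubjectRecord]:
    return random_records(1_000, seed=321)
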