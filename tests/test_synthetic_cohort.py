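import numpy as np
import pytest

from lifespan_d.chart_ingest import chart_effect_trajectory, moments_from_regression
from lifespan_d.errors import ConfigurationError, InvalidSpecError
from lifespan_d.synthetic_cohort import (
    Curve,
    GrowthModel,
    TrajectorySpec,
    lifespan_preset,
    model_from_config,
    regression_specs_from_model,
    simulate_chart,
    simulate_subjects,
    table1_dataset_layout,
    true_d,
)
from lifespan_d.window_engine import make_windows, windowed_effects


def flat_model(d=0.0, mean=500_000.0, sd=48_000.0, n=1_000, **kw):
    return GrowthModel(
        female_mean=Curve.constant(mean),
        sd_curve=Curve.constant(sd),
        trajectory=TrajectorySpec(((0.0, d),)),
        dataset_sizes={"synthetic": n},
        **kw,
    )


class TestTrajectorySpec:
    spec = TrajectorySpec(((5.0, 0.4), (24.0, 1.4)))

    def test_node_value(self):
        assert true_d(self.spec, 5.0) == 0.4

    def test_midpoint_interpolation(self):
        assert true_d(self.spec, 14.5) == pytest.approx(0.9)

    def test_clamping(self):
        assert true_d(self.spec, 30.0) == 1.4
        assert true_d(self.spec, 1.0) == 0.4

    def test_vectorized(self):
        out = true_d(self.spec, np.array([5.0, 14.5, 30.0]))
        assert out == pytest.approx([0.4, 0.9, 1.4])

    def test_non_increasing_ages_rejected(self):
        with pytest.raises(InvalidSpecError):
            TrajectorySpec(((5.0, 0.4), (5.0, 1.4)))


class TestCurves:
    def test_polynomial_ascending_order(self):
        assert Curve.polynomial([1.0, 2.0, 3.0])(2.0) == 1 + 4 + 12

    def test_logistic_midpoint(self):
        c = Curve.logistic(offset=10.0, scale=4.0, rate=1.0, midpoint=3.0)
        assert c(3.0) == pytest.approx(12.0)

    def test_piecewise_linear_clamps(self):
        c = Curve.piecewise_linear([(0, 1.0), (10, 2.0)])
        assert c(-5) == 1.0 and c(5) == 1.5 and c(20) == 2.0


class TestGrowthModel:
    def test_male_mean_offset_is_d_times_sd(self):
        m = flat_model(d=0.5)
        assert m.male_mean(30.0) - m.female_mean(30.0) == pytest.approx(0.5 * 48_000)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            flat_model(sex_ratio=1.0)
        with pytest.raises(ConfigurationError):
            flat_model(n=0)

    def test_config_round_trip(self):
        cfg = {
            "metric": "CV",
            "sex_ratio": 0.52,
            "female_mean": {"kind": "constant", "value": 5.0e5},
            "sd_curve": {"kind": "constant", "value": 4.8e4},
            "trajectory": [[5, 0.4], [24, 1.4]],
            "dataset_sizes": {"a": 10},
        }
        model = model_from_config(cfg)
        assert model.trajectory(24.0) == 1.4
        assert model.female_mean(50.0) == 5.0e5


class TestSimulateSubjects:
    def test_seeded_determinism(self):
        model = flat_model(d=1.0, n=200)
        a = simulate_subjects(model, (20.0, 30.0), seed=5)
        b = simulate_subjects(model, (20.0, 30.0), seed=5)
        assert a == b
        c = simulate_subjects(model, (20.0, 30.0), seed=6)
        assert a != c

    def test_cohort_structure(self):
        model = flat_model(d=0.5, n=300, sex_ratio=0.52)
        model = GrowthModel(
            female_mean=model.female_mean, sd_curve=model.sd_curve,
            trajectory=model.trajectory, sex_ratio=0.52,
            dataset_sizes={"a": 300, "b": 120},
        )
        records = simulate_subjects(model, (10.0, 40.0), seed=3)
        assert len(records) == 420
        assert {r.dataset_id for r in records} == {"a", "b"}
        assert all(10.0 <= r.age < 40.0 for r in records)
        assert {r.sex for r in records} == {"M", "F"}

    def test_product_carries_cv_exactly(self):
        records = simulate_subjects(flat_model(d=0.8, n=50), (20.0, 30.0), seed=9)
        for r in records:
            assert r.cortical_volume == pytest.approx(
                r.surface_area * r.mean_thickness, rel=1e-12
            )

    def test_dataset_age_ranges(self):
        model = GrowthModel(
            female_mean=Curve.constant(5e5), sd_curve=Curve.constant(4.8e4),
            trajectory=TrajectorySpec(((0.0, 0.5),)),
            dataset_sizes={"young": 100, "old": 100},
        )
        records = simulate_subjects(
            model, (5.0, 89.0), seed=2,
            dataset_age_ranges={"young": (5.0, 20.0), "old": (60.0, 89.0)},
        )
        by_ds = {"young": [], "old": []}
        for r in records:
            by_ds[r.dataset_id].append(r.age)
        assert max(by_ds["young"]) < 20.0 and min(by_ds["old"]) >= 60.0

    def test_windowed_recovery_of_constant_d(self):
        """d = 1 everywhere, one heavily populated window band: the windowed
        estimate lands within +-0.05 of truth (3 sigma at this n)."""
        model = flat_model(d=1.0, n=20_000)
        records = simulate_subjects(model, (20.0, 24.0), seed=41)
        pts = windowed_effects(records, "CV", windows=make_windows(20, 21))
        assert len(pts) == 1 and pts[0].defined
        assert pts[0].d == pytest.approx(1.0, abs=0.05)

    def test_ct_trajectory_can_be_negative_in_childhood(self):
        models = lifespan_preset(n_mri=4_000)
        records = simulate_subjects(
            models["mri_cv"], (5.0, 15.0), seed=77, ct_model=models["mri_ct"]
        )
        pts = [p for p in windowed_effects(records, "CT", windows=make_windows(5, 8))
               if p.defined]
        assert pts and all(p.d < 0 for p in pts)


class TestSimulateChart:
    def test_exact_recovery_on_noiseless_chart(self):
        models = lifespan_preset()
        rows = simulate_chart(models["postnatal"], range(0, 85), tier="postnatal")
        traj = chart_effect_trajectory(
            [r for r in rows if r.sex == "M"], [r for r in rows if r.sex == "F"]
        )
        for p in traj:
            assert p.d == pytest.approx(
                true_d(models["postnatal"].trajectory, p.age), abs=1e-9
            )

    def test_zero_trajectory_gives_zero_chart_d(self):
        rows = simulate_chart(flat_model(d=0.0), range(0, 20), tier="postnatal")
        traj = chart_effect_trajectory(
            [r for r in rows if r.sex == "M"], [r for r in rows if r.sex == "F"]
        )
        assert all(p.d == 0.0 for p in traj)

    def test_doubling_sd_changes_means_not_recovered_d(self):
        base = flat_model(d=0.7, sd=1_000.0)
        doubled = flat_model(d=0.7, sd=2_000.0)

        def recover(model):
            rows = simulate_chart(model, range(0, 10), tier="postnatal")
            return [
                p.d for p in chart_effect_trajectory(
                    [r for r in rows if r.sex == "M"],
                    [r for r in rows if r.sex == "F"],
                )
            ]

        assert recover(base) == pytest.approx(recover(doubled), rel=1e-12)
        assert simulate_chart(doubled, [5], "postnatal")[0].p50 != \
            simulate_chart(base, [5], "postnatal")[0].p50

    def test_empty_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_chart(flat_model(), [], "postnatal")


class TestRegressionEmulation:
    def test_polynomial_model_is_reproduced_exactly(self):
        model = GrowthModel(
            female_mean=Curve.polynomial([10.0, 2.0]),
            sd_curve=Curve.constant(1.0),
            trajectory=TrajectorySpec(((0.0, 0.5),)),
        )
        spec_m, spec_f = regression_specs_from_model(model, (0.0, 10.0), degree=2)
        for age in (0.0, 2.5, 10.0):
            pair = moments_from_regression(spec_m, spec_f, age)
            assert pair.mean_f == pytest.approx(10.0 + 2.0 * age, rel=1e-9)
            assert pair.mean_m - pair.mean_f == pytest.approx(0.5, rel=1e-6)
            assert pair.sd_f == pytest.approx(1.0, rel=1e-9)


class TestPresets:
    def test_lifespan_preset_trajectory_shape(self):
        models = lifespan_preset()
        cv = models["mri_cv"].trajectory
        assert true_d(cv, 5) == pytest.approx(0.4)
        assert true_d(cv, 24) == pytest.approx(1.4)
        assert true_d(cv, 89) < 1.4  # gentle late-life decline
        post = models["postnatal"].trajectory
        peaks = max(post.control_points, key=lambda p: p[1])
        assert peaks == (10.0, 1.1)
        ct = models["mri_ct"].trajectory
        assert true_d(ct, 5) < 0 and abs(true_d(ct, 13)) < 1e-12

    def test_study_mix_layout_matches_roster_scale(self):
        sizes, ranges = table1_dataset_layout(25_846)
        assert sizes["UK Biobank"] == 14_496
        assert ranges["UK Biobank"] == (45.0, 82.0)
        assert sum(sizes.values()) == pytest.approx(25_846, abs=33)
        assert len(sizes) == 33
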