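import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmkit.death import (
    DeathTimecourse,
    DeathTimepoint,
    endpoint_summary,
    lethal_fraction_series,
    read_counts_csv,
    sg_only_series,
)
from palmkit.simulate import DeathModelSpec, simulate_death_timecourse


def _course(mkate2, sg, double, dt=4.0):
    tps = [
        DeathTimepoint(t=i * dt, mkate2_pos=m, sg_pos=s, double_pos=d)
        for i, (m, s, d) in enumerate(zip(mkate2, sg, double))
    ]
    return DeathTimecourse(timepoints=tuple(tps), mode="dual")


class TestLethalFraction:
    def test_no_death_gives_zero(self):
        lf = lethal_fraction_series(_course([100, 120, 150], [0, 0, 0], [0, 0, 0]))
        assert np.allclose(lf, 0.0)

    def test_complete_death_gives_one(self):
        lf = lethal_fraction_series(_course([50, 40], [100, 100], [50, 40]))
        assert np.allclose(lf, 1.0)

    def test_hand_worked_course_with_running_sg_maximum(self):
        lf = lethal_fraction_series(
            _course([100, 80, 50], [0, 30, 60], [0, 10, 5])
        )
        assert lf == pytest.approx([0.0, 0.3, 60 / 105])

    def test_running_maximum_retains_peak_sg(self):
        # SG drops late (dead-cell disintegration); LF must not drop with it
        lf = lethal_fraction_series(
            _course([100, 50, 50], [0, 50, 10], [0, 0, 0])
        )
        assert lf[2] == pytest.approx(50 / 100)

    def test_sg_replaced_by_own_running_max_leaves_lf_unchanged(self):
        mkate2, sg, double = [100, 80, 60, 55], [0, 40, 20, 30], [0, 5, 5, 0]
        lf1 = lethal_fraction_series(_course(mkate2, sg, double))
        sgmax = np.maximum.accumulate(sg).tolist()
        lf2 = lethal_fraction_series(_course(mkate2, sgmax, double))
        assert lf1 == pytest.approx(lf2)

    def test_double_exceeding_mkate2_clamps_live(self):
        lf = lethal_fraction_series(_course([10, 10], [5, 20], [0, 15]))
        assert lf[1] == pytest.approx(1.0)  # live clamped to 0

    def test_empty_field_of_view_is_undefined_not_zero(self):
        lf = lethal_fraction_series(_course([0, 10], [0, 5], [0, 0]))
        assert np.isnan(lf[0])
        assert lf[1] == pytest.approx(5 / 15)

    def test_unsorted_timepoints_rejected(self):
        tps = (
            DeathTimepoint(t=4.0, mkate2_pos=1, sg_pos=0, double_pos=0),
            DeathTimepoint(t=0.0, mkate2_pos=1, sg_pos=0, double_pos=0),
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            DeathTimecourse(timepoints=tps, mode="dual")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DeathTimepoint(t=0.0, mkate2_pos=-1, sg_pos=0, double_pos=0)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_lf_bounded_in_unit_interval_wherever_defined(self, counts):
        mkate2 = [c[0] for c in counts]
        sg = [c[1] for c in counts]
        double = [min(c[2], c[1]) for c in counts]
        lf = lethal_fraction_series(_course(mkate2, sg, double))
        defined = lf[~np.isnan(lf)]
        assert ((defined >= 0) & (defined <= 1)).all()


class TestSgOnly:
    def test_running_max_is_monotone_envelope(self):
        tps = tuple(
            DeathTimepoint(t=float(i * 4), sg_pos=v) for i, v in enumerate([0, 5, 3])
        )
        tc = DeathTimecourse(timepoints=tps, mode="sg-only")
        sg, sgmax = sg_only_series(tc)
        assert sg.tolist() == [0, 5, 3]
        assert sgmax.tolist() == [0, 5, 5]

    def test_all_zero_counts(self):
        tps = tuple(DeathTimepoint(t=float(i), sg_pos=0) for i in range(3))
        _, sgmax = sg_only_series(DeathTimecourse(timepoints=tps, mode="sg-only"))
        assert sgmax.tolist() == [0, 0, 0]

    def test_matches_prefix_maximum_oracle(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 300, size=25).astype(float)
        tps = tuple(
            DeathTimepoint(t=float(i * 4), sg_pos=v) for i, v in enumerate(values)
        )
        _, sgmax = sg_only_series(DeathTimecourse(timepoints=tps, mode="sg-only"))
        oracle = [max(values[: i + 1]) for i in range(len(values))]
        assert sgmax.tolist() == oracle


class TestEndpointSummary:
    def test_flat_zero_course(self):
        times = np.arange(0, 100, 4.0)
        summary = endpoint_summary(np.zeros_like(times), times)
        assert summary["max_lf"] == 0.0
        assert summary["auc"] == 0.0
        assert summary["t_half"] is None

    def test_linear_crossing_interpolation(self):
        summary = endpoint_summary([0.0, 1.0], [0.0, 10.0])
        assert summary["t_half"] == pytest.approx(5.0)
        assert summary["auc"] == pytest.approx(5.0)

    def test_all_undefined_series_is_error(self):
        with pytest.raises(ValueError):
            endpoint_summary([np.nan, np.nan], [0.0, 4.0])

    def test_simulated_half_death_time_within_one_frame(self):
        spec = DeathModelSpec(noise="none")
        tc, analytic = simulate_death_timecourse(spec)
        lf = lethal_fraction_series(tc)
        summary = endpoint_summary(lf, tc.times)
        # true half-death: dead/(live+dead) = 0.5 => lam*(t-t_on) = ln 2
        t_half_true = spec.t_on + np.log(2) / spec.lam
        assert abs(summary["t_half"] - t_half_true) <= spec.frame_interval


class TestSimulatedCourses:
    def test_no_hazard_limit(self):
        tc, analytic = simulate_death_timecourse(DeathModelSpec(lam=0.0))
        assert np.allclose(analytic, 0.0)
        assert np.allclose(lethal_fraction_series(tc), 0.0)

    def test_saturation_limit(self):
        tc, analytic = simulate_death_timecourse(
            DeathModelSpec(lam=2.0, horizon=200.0)
        )
        assert analytic[-1] > 0.999
        assert lethal_fraction_series(tc)[-1] > 0.999

    @pytest.mark.parametrize(
        "spec",
        [
            DeathModelSpec(),
            DeathModelSpec(n0=50, r=0.05, t_on=12, lam=0.2, tau=8, horizon=72),
            DeathModelSpec(r=0.0, tau=0.0),
        ],
    )
    def test_noise_free_course_matches_analytic_lf_to_1e9(self, spec):
        tc, analytic = simulate_death_timecourse(spec)
        lf = lethal_fraction_series(tc)
        assert np.nanmax(np.abs(lf - analytic)) < 1e-9

    def test_poisson_mean_lf_matches_analytic_within_3_se(self):
        spec = DeathModelSpec(noise="poisson")
        _, analytic = simulate_death_timecourse(spec)
        courses = []
        for seed in range(100):
            tc, _ = simulate_death_timecourse(
                DeathModelSpec(noise="poisson", seed=seed)
            )
            courses.append(lethal_fraction_series(tc))
        courses = np.array(courses)
        mean = courses.mean(axis=0)
        se = courses.std(axis=0, ddof=1) / np.sqrt(courses.shape[0])
        # frames before onset have zero variance and exact agreement
        active = se > 0
        assert np.allclose(mean[~active], analytic[~active])
        assert (np.abs(mean[active] - analytic[active]) <= 3 * se[active]).all()

    def test_count_invariants_hold_under_poisson_noise(self):
        for seed in range(5):
            tc, _ = simulate_death_timecourse(
                DeathModelSpec(noise="poisson", seed=seed)
            )
            for tp in tc.timepoints:
                assert tp.double_pos <= tp.sg_pos
                assert tp.double_pos <= tp.mkate2_pos


def test_counts_csv_round_trip(tmp_path):
    import pandas as pd

    tc, _ = simulate_death_timecourse(DeathModelSpec(noise="poisson", seed=2))
    rows = [
        {"well": "A1", "t_hours": tp.t, "mkate2_pos": tp.mkate2_pos,
         "sg_pos": tp.sg_pos, "double_pos": tp.double_pos}
        for tp in tc.timepoints
    ]
    path = tmp_path / "counts.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    courses = read_counts_csv(path, mode="dual")
    assert set(courses) == {"A1"}
    assert np.allclose(
        lethal_fraction_series(courses["A1"]), lethal_fraction_series(tc),
        equal_nan=True,
    )
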