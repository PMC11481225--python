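"""Degradation, concordance, linear/pMC interpolation and calibration."""

import warnings

import numpy as np
import pytest

import motilikit as mk
from motilikit.harmonization import (
    compare_parameter_distributions,
    dunn_test,
)
from motilikit.aprw import PARAMETER_NAMES, fit_dataset
from conftest import build_reference_cohort


def _traj(t, x, y, interval):
    return mk.Trajectory("cell", "c1", np.asarray(t, float),
                         np.asarray(x, float), np.asarray(y, float), interval)


def _line_traj(n, dt, slope=1.0):
    t = dt * np.arange(n)
    return _traj(t, slope * t, np.zeros(n), dt)


class TestDegradeResolution:
    def test_every_fifth_point_retained(self):
        traj = _line_traj(51, 2.0)  # 2-min trajectory
        out = mk.degrade_resolution(traj, 10.0)
        assert out.interval == 10.0
        np.testing.assert_array_equal(out.x, traj.x[::5])

    def test_identity_at_source_interval(self):
        traj = _line_traj(31, 5.0)
        out = mk.degrade_resolution(traj, 5.0)
        np.testing.assert_array_equal(out.x, traj.x)

    def test_sample_count_by_index_arithmetic(self):
        traj = _line_traj(31, 5.0)
        out = mk.degrade_resolution(traj, 10.0)
        assert len(out) == 16

    def test_non_multiple_target_raises(self):
        with pytest.raises(ValueError, match="multiple"):
            mk.degrade_resolution(_line_traj(31, 5.0), 12.5)


class TestGeometricConcordance:
    def test_collinear_path_gives_zero(self):
        ref = _line_traj(11, 1.0)
        cand = mk.degrade_resolution(ref, 2.0)
        total, mean = mk.geometric_concordance(ref, cand)
        assert total == pytest.approx(0.0)
        assert mean == pytest.approx(0.0)

    def test_identical_sampling_gives_zero(self):
        ref = _line_traj(11, 1.0)
        total, _ = mk.geometric_concordance(ref, ref)
        assert total == 0.0

    def test_right_angle_path_single_triangle(self):
        # (0,0) -> (1,0) -> (1,1) at 1-min sampling, degraded to 2-min:
        # single triangle with area 0.5 by the shoelace formula
        ref = _traj([0, 1, 2], [0, 1, 1], [0, 0, 1], 1.0)
        cand = mk.degrade_resolution(ref, 2.0)
        total, mean = mk.geometric_concordance(ref, cand)
        assert total == pytest.approx(0.5)
        assert mean == pytest.approx(0.5)

    def test_concordance_nonnegative_on_random_paths(self, rng):
        from conftest import random_trajectory

        for _ in range(10):
            ref = random_trajectory(rng, 21, dt=1.0)
            cand = mk.degrade_resolution(ref, 4.0)
            total, mean = mk.geometric_concordance(ref, cand)
            assert total >= 0.0
            assert mean >= 0.0

    def test_disjoint_grids_raise(self):
        ref = _line_traj(11, 1.0)
        shifted = _traj(ref.t + 0.5, ref.x, ref.y, 1.0)
        with pytest.raises(ValueError, match="subset"):
            mk.geometric_concordance(ref, shifted)


class TestLinearInterpolate:
    def test_symmetric_midpoint(self):
        traj = _traj([0.0, 8.0], [0.0, 8.0], [0.0, 0.0], 8.0)
        out = mk.linear_interpolate(traj, 4.0)
        np.testing.assert_allclose(out.t, [0.0, 4.0, 8.0])
        np.testing.assert_allclose(out.x, [0.0, 4.0, 8.0])

    def test_constant_position_stays_constant(self):
        t = 8.0 * np.arange(5)
        traj = _traj(t, np.full(5, 3.0), np.full(5, -1.0), 8.0)
        out = mk.linear_interpolate(traj, 2.0)
        assert np.all(out.x == 3.0)
        assert np.all(out.y == -1.0)

    def test_asymmetric_ramp_8_to_6(self):
        # on the line x = t the interpolated x values equal their times
        t = 8.0 * np.arange(7)
        traj = _traj(t, t, np.zeros(7), 8.0)
        out = mk.linear_interpolate(traj, 6.0)
        assert out.interval == 6.0
        np.testing.assert_allclose(out.x, out.t, atol=1e-12)

    def test_observed_samples_preserved_exactly(self, rng):
        from conftest import random_trajectory

        traj = random_trajectory(rng, 7, dt=8.0)
        out = mk.linear_interpolate(traj, 4.0)
        np.testing.assert_array_equal(out.x[::2], traj.x)
        np.testing.assert_array_equal(out.y[::2], traj.y)


class TestPMCInterpolate:
    def test_seeded_determinism(self, rng):
        from conftest import random_trajectory

        traj = random_trajectory(rng, 7, dt=10.0)
        cfg = mk.PMCConfig(rng_seed=42)
        a = mk.pmc_interpolate(traj, 5.0, cfg)
        b = mk.pmc_interpolate(traj, 5.0, cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_perturbation_only_in_dominant_dimension(self):
        # chord dominated by x: the y coordinate must equal the linear value
        traj = _traj([0.0, 10.0], [0.0, 10.0], [0.0, 1.0], 10.0)
        cfg = mk.PMCConfig(rng_seed=0)
        lin = mk.linear_interpolate(traj, 5.0)
        pmc = mk.pmc_interpolate(traj, 5.0, cfg)
        assert pmc.y[1] == lin.y[1]
        assert pmc.x[1] != lin.x[1]

    def test_tie_perturbs_both_dimensions(self):
        traj = _traj([0.0, 10.0], [0.0, 10.0], [0.0, 10.0], 10.0)
        lin = mk.linear_interpolate(traj, 5.0)
        pmc = mk.pmc_interpolate(traj, 5.0, mk.PMCConfig(rng_seed=1))
        assert pmc.x[1] != lin.x[1]
        assert pmc.y[1] != lin.y[1]

    def test_deterministic_law_matches_chord_over_factor(self):
        traj = _traj([0.0, 10.0], [0.0, 10.0], [0.0, 0.0], 10.0)
        cfg = mk.PMCConfig(pmc_factor=2.0, perturbation_law="deterministic")
        out = mk.pmc_interpolate(traj, 5.0, cfg)
        # linear midpoint 5.0 plus chord (10) / factor (2)
        assert out.x[1] == pytest.approx(10.0)

    def test_observed_samples_are_fixed_points(self, rng):
        from conftest import random_trajectory

        traj = random_trajectory(rng, 7, dt=10.0)
        out = mk.pmc_interpolate(traj, 5.0, mk.PMCConfig(rng_seed=3))
        np.testing.assert_array_equal(out.x[::2], traj.x)

    def test_default_factor_is_calibrated_value(self):
        assert mk.PMCConfig().pmc_factor == 2.01


class TestHarmonizeDataset:
    def test_matching_interval_passthrough(self):
        ts = build_reference_cohort(2, n_steps=10, seed0=3)
        out, prov = mk.harmonize_dataset(ts, target_interval=5.0)
        assert set(prov["method"]) == {"passthrough"}
        np.testing.assert_array_equal(
            out.trajectories[0].x, ts.trajectories[0].x
        )

    def test_finer_condition_degraded(self):
        traj = _line_traj(101, 1.0)
        ts = mk.TrajectorySet([traj], {})
        out, prov = mk.harmonize_dataset(ts, target_interval=5.0)
        assert prov["method"].iloc[0] == "degrade"
        assert out.trajectories[0].interval == 5.0
        assert len(out.trajectories[0]) == 21

    def test_coarser_condition_pmc_interpolated(self):
        traj = _line_traj(11, 10.0)
        out, prov = mk.harmonize_dataset(
            mk.TrajectorySet([traj], {}), target_interval=5.0
        )
        assert prov["method"].iloc[0] == "pmc"
        assert out.trajectories[0].interval == 5.0
        # observed 10-min samples survive exactly
        np.testing.assert_array_equal(out.trajectories[0].x[::2], traj.x)

    def test_incommensurate_2min_to_5min_grid(self):
        traj = _line_traj(76, 2.0)  # 150 min at 2-min interval
        out, prov = mk.harmonize_dataset(
            mk.TrajectorySet([traj], {}), target_interval=5.0
        )
        assert prov["method"].iloc[0] == "pmc"
        res = out.trajectories[0]
        assert res.interval == 5.0
        assert len(res) == 31
        # times that are multiples of 10 coincide with observed samples
        np.testing.assert_allclose(res.x[::2], traj.x[::5])


class TestDunnAndCalibration:
    def test_dunn_flags_a_shifted_group(self, rng):
        same = [rng.normal(0, 1, 80) for _ in range(2)]
        shifted = rng.normal(3.0, 1, 80)
        pvals = dunn_test([same[0], same[1], shifted], [(0, 1), (0, 2)])
        assert pvals[0] > 0.05
        assert pvals[1] < 0.01

    def test_identity_reconstruction_passes_comparison(self):
        cohort = build_reference_cohort(30, n_steps=30, seed0=11)
        params = fit_dataset(cohort).dropna()
        report = compare_parameter_distributions(
            params, {"identical": params.copy()}
        )
        assert not report["significant"].any()

    def test_calibration_selects_passing_factor(self):
        # desk-scale analogue of the pMC-factor calibration: 2-min
        # trajectories degraded to 10 min, reconstructed, refitted
        cohort = build_reference_cohort(
            50, n_steps=75, seed0=21, condition_prefix="hires"
        )
        fine = mk.TrajectorySet(
            [
                mk.Trajectory(t.cell_id, t.condition_id, t.t * 0.4, t.x,
                              t.y, 2.0)
                for t in cohort
            ],
            {},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = mk.calibrate_pmc_factor(
                fine, candidates=(2.0, 2.01), degraded_interval=10.0,
            )
        assert result.factor in (2.0, 2.01)
        assert set(result.report["parameter"]) == set(PARAMETER_NAMES)
        if result.all_pass:
            passing = result.report.groupby("variant")["significant"].sum()
            assert passing[f"{result.factor:g}"] == 0
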