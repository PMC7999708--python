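"""Generator tests: kinetics, energy partition, spectra, stacks, relaxation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluorsense import simulate
from fluorsense.config import (
    BaselineParams,
    EmissionPeak,
    ImagingParams,
    SimulationConfig,
    TransientDip,
    paper_preset,
)
from fluorsense.imaging import intensity_timecourse
from fluorsense.simulate import (
    fluorescence_yield,
    relaxation_partition,
    simulate_cfi_stack,
    simulate_npq_relaxation,
    simulate_phipsii_timecourse,
    simulate_reflectance_series,
)


# ---------------------------------------------------------------------------
# PSII yield kinetics
# ---------------------------------------------------------------------------

class TestPhiPSIITimecourse:
    def test_starts_near_phi0_when_lag_dominates(self):
        cfg = SimulationConfig(lag_min=400, tau_min=20)
        phi = simulate_phipsii_timecourse(cfg)
        assert abs(phi.iloc[0] - cfg.phi0) < 1e-3

    def test_saturates_to_phi_min(self):
        cfg = SimulationConfig(lag_min=60, tau_min=20)
        phi = simulate_phipsii_timecourse(cfg)
        assert abs(phi.iloc[-1] - cfg.phi_min) < 1e-3

    def test_exact_midpoint_at_lag(self):
        # binary-exact parameter values so the midpoint identity is exact
        cfg = SimulationConfig(phi0=0.75, phi_min=0.25, lag_min=150)
        phi = simulate_phipsii_timecourse(cfg)
        assert phi.loc[150.0] == (0.75 + 0.25) / 2

    def test_monotone_non_increasing(self):
        phi = simulate_phipsii_timecourse(paper_preset(1))
        assert np.all(np.diff(phi.values) <= 0)

    def test_invalid_config_names_parameter(self):
        with pytest.raises(ValueError, match="phi0"):
            SimulationConfig(phi0=0.3, phi_min=0.5)
        with pytest.raises(ValueError, match="interval"):
            SimulationConfig(duration_min=480, interval_min=13)
        with pytest.raises(ValueError, match="k_f"):
            SimulationConfig(k_f=1.5)


# ---------------------------------------------------------------------------
# energy partition
# ---------------------------------------------------------------------------

class TestEnergyPartition:
    def test_full_photochemistry_leaves_nothing(self):
        p = fluorescence_yield(1.0, 0.1)
        assert p.phi_f == 0.0 and p.phi_heat == 0.0

    def test_closed_centres_split(self):
        p = fluorescence_yield(0.0, 0.1)
        assert p.phi_f == pytest.approx(0.1, abs=1e-15)
        assert p.phi_heat == pytest.approx(0.9, abs=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fluorescence_yield(1.2, 0.1)
        with pytest.raises(ValueError):
            fluorescence_yield(0.5, 0.0)

    @given(
        phi=st.floats(0.0, 1.0, allow_nan=False),
        k_f=st.floats(0.001, 0.999, allow_nan=False),
    )
    def test_partition_sums_to_one(self, phi, k_f):
        p = fluorescence_yield(phi, k_f)
        assert abs(p.phi_psii + p.phi_heat + p.phi_f - 1.0) <= 1e-12
        for v in (p.phi_psii, p.phi_heat, p.phi_f):
            assert 0.0 <= v <= 1.0

    @given(
        npq=st.floats(0.0, 10.0, allow_nan=False),
        k_f=st.floats(0.001, 0.999, allow_nan=False),
        k_p=st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_relaxation_partition_sums_to_one(self, npq, k_f, k_p):
        p = relaxation_partition(npq, k_f, k_p)
        assert abs(p.phi_psii + p.phi_heat + p.phi_f - 1.0) <= 1e-12


# ---------------------------------------------------------------------------
# reflectance series
# ---------------------------------------------------------------------------

class TestReflectanceSeries:
    def test_no_emission_no_noise_is_constant(self):
        cfg = SimulationConfig(
            peak680=EmissionPeak(680, 0.0, 10),
            peak740=EmissionPeak(740, 0.0, 18),
            baseline=BaselineParams(bleach_fraction=0.0),
            dip=TransientDip(enabled=False),
        ).without_noise()
        series = simulate_reflectance_series(cfg)
        assert np.all(series.values == series.values[:, :1])

    def test_grid_spans_instrument_range(self, nf_series):
        assert nf_series.wavelengths[0] == 450.0
        assert nf_series.wavelengths[-1] == 770.0

    def test_all_values_positive(self, nf_series):
        assert np.all(nf_series.values > 0)

    def test_far_red_channel_increases_after_lag(self, nf_series, nf_cfg):
        ch = nf_series.at_wavelength(740.0)
        after = nf_series.times > nf_cfg.lag_min
        assert np.all(np.diff(ch.values[after]) > 0)

    def test_noise_free_identical_across_seeds(self, nf_cfg):
        a = simulate_reflectance_series(nf_cfg)
        b = simulate_reflectance_series(nf_cfg.with_seed(99))
        assert np.array_equal(a.values, b.values)

    def test_seeded_runs_bit_reproducible(self, paper_cfg):
        a = simulate_reflectance_series(paper_cfg)
        b = simulate_reflectance_series(paper_cfg)
        assert np.array_equal(a.values, b.values)
        c = simulate_reflectance_series(paper_cfg.with_seed(2))
        assert not np.array_equal(a.values, c.values)


# ---------------------------------------------------------------------------
# image stack
# ---------------------------------------------------------------------------

class TestCFIStack:
    def test_frames_are_8bit_in_range(self, small_stack):
        stack, _ = small_stack
        assert stack.frames.dtype == np.uint8
        assert stack.frames.min() >= 0 and stack.frames.max() <= 255

    def test_no_damage_means_constant_stack(self):
        cfg = SimulationConfig(
            lag_min=5000, duration_min=60, interval_min=15,
            imaging=ImagingParams(shape=(96, 128)),
        ).without_noise()
        stack, _ = simulate_cfi_stack(cfg)
        assert np.all(stack.frames == stack.frames[:1])

    def test_rejects_frames_too_small_for_leaf(self):
        with pytest.raises(ValueError, match="shape"):
            ImagingParams(shape=(32, 32))

    def test_damage_total_non_decreasing(self, small_stack):
        _, truth = small_stack
        totals = truth.damage.reshape(truth.damage.shape[0], -1).sum(axis=1)
        assert np.all(np.diff(totals) >= 0)

    def test_distance_map_matches_bruteforce_minimum(self, small_stack, small_cfg, rng):
        """Oracle: per-pixel python loop over every vein sample."""
        _, truth = small_stack
        lf = small_cfg.imaging.lamina_factor
        yy, xx = np.nonzero(truth.leaf_mask)
        pick = rng.choice(yy.size, size=100, replace=False)
        for r, c in zip(yy[pick], xx[pick]):
            best = min(
                dv + lf * np.hypot(r - pr, c - pc)
                for (pr, pc), dv in zip(truth.vein_points, truth.vein_distance)
            )
            assert truth.distance_map[r, c] == pytest.approx(best, abs=1e-9)

    def test_vein_first_spread(self, nf_default_stack, nf_cfg):
        """Midvein-adjacent tissue lights up before the lamina interior."""
        from scipy.spatial import cKDTree

        stack, truth = nf_default_stack
        t = stack.times
        k = int(np.argmin(np.abs(t - (nf_cfg.lag_min + 60))))
        tree = cKDTree(truth.vein_points)
        yy, xx = np.nonzero(truth.leaf_mask)
        d_euc, _ = tree.query(np.stack([yy, xx], axis=1))
        frame = stack.frames[k].astype(float)
        adjacent = frame[yy[d_euc < 4], xx[d_euc < 4]].mean()
        interior = frame[yy[d_euc > 20], xx[d_euc > 20]].mean()
        assert adjacent > interior

    def test_suggested_roi_inside_leaf(self, small_stack):
        _, truth = small_stack
        sl = truth.suggested_roi.slices()
        assert truth.leaf_mask[sl].all()

    def test_noise_free_stack_identical_across_seeds(self, small_cfg):
        a, _ = simulate_cfi_stack(small_cfg)
        b, _ = simulate_cfi_stack(small_cfg.with_seed(17))
        assert np.array_equal(a.frames, b.frames)


# ---------------------------------------------------------------------------
# NPQ relaxation
# ---------------------------------------------------------------------------

class TestNPQRelaxation:
    def test_initial_condition(self, nf_relaxation, nf_cfg):
        assert nf_relaxation.npq_true.iloc[0] == nf_cfg.relaxation.npq0

    def test_full_relaxation_limit(self):
        cfg = SimulationConfig(
            imaging=ImagingParams(shape=(96, 128)),
            relaxation=dataclasses.replace(
                SimulationConfig().relaxation, tau_npq_min=0.5
            ),
        ).without_noise()
        run = simulate_npq_relaxation(cfg)
        assert run.npq_true.iloc[-1] < 1e-9
        dark_phi = cfg.relaxation.k_p / (1.0 + cfg.relaxation.k_p)
        assert run.phi_psii_true.iloc[-1] == pytest.approx(dark_phi, abs=1e-9)

    def test_pixel_up_npq_down(self, nf_relaxation):
        course = intensity_timecourse(
            nf_relaxation.stack, nf_relaxation.suggested_roi
        )
        assert np.all(np.diff(course["mean_intensity"].values) > 0)
        assert np.all(np.diff(nf_relaxation.npq_true.values) < 0)

    def test_negative_npq0_rejected(self):
        with pytest.raises(ValueError, match="npq0"):
            SimulationConfig(
                relaxation=dataclasses.replace(
                    SimulationConfig().relaxation, npq0=-1.0
                )
            )


def test_atrazine_run_bundles_consistent_clocks(small_cfg):
    run = simulate.simulate_atrazine_run(small_cfg)
    assert np.array_equal(run.spectra.times, run.stack.times)
    assert np.array_equal(run.pam["time_min"].values, run.stack.times)
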