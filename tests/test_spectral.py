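"""Spectral statistics: normalization, nARFS, variability, selection, FBSI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluorsense.spectral import (
    FluorescenceBand,
    IndexWavelengths,
    NormalizedSpectrumSeries,
    SpectrumSeries,
    compute_fbsi,
    compute_narfs,
    normalize_to_baseline,
    read_spectrum_csv,
    select_index_wavelengths,
    wavelength_variability,
    write_spectrum_csv,
)


def _series(wl, times, values, **kw):
    return SpectrumSeries(
        wavelengths=np.asarray(wl, float),
        times=np.asarray(times, float),
        values=np.asarray(values, float),
        **kw,
    )


def _norm(wl, times, values):
    return NormalizedSpectrumSeries(
        wavelengths=np.asarray(wl, float),
        times=np.asarray(times, float),
        values=np.asarray(values, float),
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_self_normalization_is_ones(self):
        v = np.tile([[0.2], [0.5], [0.8]], (1, 4))
        out = normalize_to_baseline(_series([500, 600, 700], [0, 15, 30, 45], v))
        assert np.all(out.values == 1.0)

    def test_simple_ratio(self):
        out = normalize_to_baseline(
            _series([500], [0, 15], [[0.10, 0.15]])
        )
        assert out.values[0, 1] == pytest.approx(1.5, abs=1e-15)

    def test_baseline_column_exactly_one(self, nf_norm):
        assert np.all(nf_norm.values[:, 0] == 1.0)

    def test_matches_elementwise_division_oracle(self, nf_series, nf_norm):
        for i in range(nf_series.wavelengths.size):
            for j in range(nf_series.times.size):
                expected = nf_series.values[i, j] / nf_series.values[i, 0]
                assert abs(nf_norm.values[i, j] - expected) <= 1e-12

    def test_series_without_time_zero_rejected(self):
        with pytest.raises(ValueError, match="t = 0"):
            _series([500], [15, 30], [[0.1, 0.2]])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            _series([500, 600], [0, 15], [[0.1, 0.2], [0.0, 0.3]])


# ---------------------------------------------------------------------------
# nARFS
# ---------------------------------------------------------------------------

class TestNARFS:
    def test_default_band_edges(self):
        band = FluorescenceBand()
        assert band.lo == 669.8 and band.hi == 760.7

    def test_time_zero_is_exactly_one(self, nf_norm):
        narfs = compute_narfs(nf_norm)
        assert narfs.iloc[0] == 1.0

    def test_mean_of_inband_channels(self):
        norm = _norm(
            [660, 700, 720, 750],
            [0, 15],
            [[1, 1.1], [1, 1.0], [1, 1.2], [1, 1.4]],
        )
        narfs = compute_narfs(norm, FluorescenceBand(669.8, 760.7))
        assert narfs.iloc[1] == pytest.approx(1.2, abs=1e-15)

    def test_band_edges_inclusive(self):
        norm = _norm([669.8, 760.7], [0, 15], [[1, 2.0], [1, 4.0]])
        narfs = compute_narfs(norm, FluorescenceBand(669.8, 760.7))
        assert narfs.iloc[1] == 3.0

    def test_empty_band_rejected(self, nf_norm):
        # a sliver between the last two grid channels holds < 2 channels
        with pytest.raises(ValueError, match="channels"):
            compute_narfs(nf_norm, FluorescenceBand(769.0, 769.9))

    def test_matches_bruteforce_mean_oracle(self, nf_norm):
        band = FluorescenceBand()
        narfs = compute_narfs(nf_norm, band)
        for j, t in enumerate(nf_norm.times):
            total, n = 0.0, 0
            for i, wl in enumerate(nf_norm.wavelengths):
                if band.lo <= wl <= band.hi:
                    total += nf_norm.values[i, j]
                    n += 1
            assert abs(narfs.iloc[j] - total / n) <= 1e-12


# ---------------------------------------------------------------------------
# variability and wavelength selection
# ---------------------------------------------------------------------------

class TestVariability:
    def test_constant_series_has_zero_sd(self):
        norm = _norm([500, 600], [0, 15, 30], np.ones((2, 3)))
        assert np.all(wavelength_variability(norm).values == 0.0)

    def test_sample_std_two_values(self):
        norm = _norm([500], [0, 15], [[1.0, 1.2]])
        sd = wavelength_variability(norm, min_timepoints=2)
        assert sd.iloc[0] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_too_few_timepoints_rejected(self):
        norm = _norm([500], [0, 15], [[1.0, 1.2]])
        with pytest.raises(ValueError, match="timepoints"):
            wavelength_variability(norm)

    def test_extremes_fall_in_expected_bands(self, nf_norm):
        """Brute-force std over every channel: the most responsive channel is
        far-red (fluorescence emission) and the flattest is green."""
        sd = wavelength_variability(nf_norm)
        brute = np.array(
            [np.std(nf_norm.values[i], ddof=1)
             for i in range(nf_norm.wavelengths.size)]
        )
        assert np.allclose(sd.values, brute, atol=1e-12)
        wl = nf_norm.wavelengths
        assert 720 <= wl[np.argmax(brute)] <= 755
        assert 500 <= wl[np.argmin(brute)] <= 620


class TestSelectIndexWavelengths:
    def test_single_strict_maximum_is_selected(self):
        wl = np.array([500.0, 600.0, 700.0, 750.0])
        t = np.array([0.0, 15.0, 30.0])
        values = np.ones((4, 3))
        values[2] = [1.0, 1.2, 1.5]   # only channel that moves
        values[0] = [1.0, 1.001, 1.002]
        norm = _norm(wl, t, values)
        sd = wavelength_variability(norm)
        idx = select_index_wavelengths(sd, norm, np.array([0.7, 0.5, 0.2]))
        assert idx.lambda_signal == 700.0

    def test_noise_free_recovers_far_red_and_green(self, nf_norm, nf_phi):
        sd = wavelength_variability(nf_norm)
        idx = select_index_wavelengths(sd, nf_norm, nf_phi.values)
        spacing = np.diff(nf_norm.wavelengths).max()
        assert abs(idx.lambda_signal - 740.0) <= 2 * spacing
        assert 500 <= idx.lambda_reference <= 620
        assert idx.candidates  # audit list is returned

    def test_no_candidate_above_threshold_errors(self):
        # variability strictly increasing across channels: no interior maximum
        values = np.array(
            [[1.0, 1.001, 0.999],
             [1.0, 1.002, 0.998],
             [1.0, 1.003, 0.997]]
        )
        norm = _norm([500, 600, 700], [0, 15, 30], values)
        sd = wavelength_variability(norm)
        with pytest.raises(ValueError, match="threshold"):
            select_index_wavelengths(sd, norm, np.array([0.7, 0.5, 0.2]))

    def test_signal_equal_reference_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            IndexWavelengths(741.2, 741.2)


# ---------------------------------------------------------------------------
# FBSI
# ---------------------------------------------------------------------------

class TestFBSI:
    def _two_channel(self, sig, ref):
        """Series with channels at 548.9 and 741.2 nm and given time rows."""
        return _series(
            [548.9, 741.2], [0, 15],
            np.array([ref, sig], dtype=float),
        )

    def test_equal_bands_give_zero(self):
        series = self._two_channel([0.3, 0.3], [0.3, 0.3])
        fbsi = compute_fbsi(series, IndexWavelengths(741.2, 548.9))
        assert np.all(fbsi.values == 0.0)

    def test_arithmetic_example(self):
        series = self._two_channel(sig=[0.6, 0.6], ref=[0.2, 0.2])
        fbsi = compute_fbsi(series, IndexWavelengths(741.2, 548.9))
        assert fbsi.iloc[0] == pytest.approx(0.5, abs=1e-15)

    def test_limit_as_reference_vanishes(self):
        series = self._two_channel(sig=[0.6, 0.6], ref=[1e-12, 1e-12])
        fbsi = compute_fbsi(series, IndexWavelengths(741.2, 548.9))
        assert fbsi.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_values_strictly_inside_unit_interval(self, nf_series):
        fbsi = compute_fbsi(nf_series, IndexWavelengths(741.2, 548.9))
        assert np.all(np.abs(fbsi.values) < 1.0)

    @given(
        s=st.floats(1e-6, 1e3), r=st.floats(1e-6, 1e3),
    )
    def test_antisymmetry(self, s, r):
        series = self._two_channel(sig=[s, s], ref=[r, r])
        fwd = compute_fbsi(series, IndexWavelengths(741.2, 548.9))
        rev = compute_fbsi(series, IndexWavelengths(548.9, 741.2))
        assert np.all(fwd.values == -rev.values)

    @given(
        s=st.floats(1e-3, 1e3), r=st.floats(1e-3, 1e3),
        c=st.floats(1e-3, 1e3),
    )
    def test_gain_invariance(self, s, r, c):
        base = self._two_channel(sig=[s, s], ref=[r, r])
        scaled = self._two_channel(sig=[c * s, c * s], ref=[c * r, c * r])
        idx = IndexWavelengths(741.2, 548.9)
        f0 = compute_fbsi(base, idx).iloc[0]
        f1 = compute_fbsi(scaled, idx).iloc[0]
        assert f1 == pytest.approx(f0, abs=1e-12)

    def test_monotone_with_fluorescence_on_synthetic(self, nf_series, nf_cfg):
        """After the onset lag the index rises with the fluorescence yield."""
        fbsi = compute_fbsi(nf_series, IndexWavelengths(741.2, 548.9))
        after = nf_series.times > nf_cfg.lag_min
        assert np.all(np.diff(fbsi.values[after]) > 0)


# ---------------------------------------------------------------------------
# channel resolution and I/O
# ---------------------------------------------------------------------------

def test_nearest_channel_tie_breaks_low():
    series = _series([500.0, 504.0], [0], [[0.1], [0.2]])
    assert series.channel_index(502.0) == 0  # equidistant -> lower wavelength


def test_spectrum_csv_roundtrip(tmp_path, nf_series):
    path = tmp_path / "spectra.csv"
    write_spectrum_csv(nf_series, path)
    back = read_spectrum_csv(path, replication_id=nf_series.replication_id)
    assert np.array_equal(back.times, nf_series.times)
    assert np.allclose(back.values, nf_series.values, atol=1e-12)
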