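"""Spectral analysis: baseline normalization, nARFS, variability, FBSI.

The measured quantity is leaf "reflectance" that in reality mixes true
reflectance with chlorophyll-a fluorescence emission.  Normalizing every
scan to the scan taken at application time isolates the temporal change;
averaging the normalized values over the chlorophyll-fluorescence waveband
(669.8-760.7 nm) gives the nARFS statistic.  The per-wavelength standard
deviation of the normalized series identifies fluorescence-responsive
channels, from which a deployable two-band normalized-difference index
(the FBSI) is built: (R_signal - R_reference)/(R_signal + R_reference),
with the paper-of-record choice being 741.2 nm over 548.9 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr

__all__ = [
    "SpectrumSeries",
    "NormalizedSpectrumSeries",
    "FluorescenceBand",
    "IndexWavelengths",
    "normalize_to_baseline",
    "compute_narfs",
    "wavelength_variability",
    "select_index_wavelengths",
    "compute_fbsi",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


def _nearest_channel(wavelengths: np.ndarray, target_nm: float) -> int:
    """Nearest grid channel; on an exact tie the lower wavelength wins."""
    d = np.abs(wavelengths - target_nm)
    return int(np.argmin(d))  # argmin returns the first (lower-wavelength) tie


@dataclass(frozen=True)
class SpectrumSeries:
    """Wavelength x time matrix of measured reflectance/fluorescence.

    ``values[i, j]`` is the reading at ``wavelengths[i]`` and ``times[j]``
    (minutes since treatment; the t = 0 scan must be present, since it is
    the normalization baseline).
    """

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray
    replication_id: str = "R1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths",
                           np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        wl, t, v = self.wavelengths, self.times, self.values
        if v.shape != (wl.size, t.size):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"({wl.size} wavelengths, {t.size} times)"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("the t = 0 baseline scan must be present")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        if np.any(v <= 0):
            raise ValueError("all measured values must be > 0")

    def channel_index(self, target_nm: float) -> int:
        return _nearest_channel(self.wavelengths, target_nm)

    def at_wavelength(self, target_nm: float) -> pd.Series:
        """Time series at the grid channel nearest ``target_nm``."""
        i = self.channel_index(target_nm)
        return pd.Series(
            self.values[i], index=pd.Index(self.times, name="time_min"),
            name=f"{self.wavelengths[i]:.1f}nm",
        )


@dataclass(frozen=True)
class NormalizedSpectrumSeries:
    """Spectrum series divided element-wise by its t = 0 column."""

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray
    replication_id: str = "R1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths",
                           np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("normalized values must be finite and > 0")
        if not np.all(self.values[:, 0] == 1.0):
            raise ValueError("normalized baseline column must be exactly 1")

    def channel_index(self, target_nm: float) -> int:
        return _nearest_channel(self.wavelengths, target_nm)

    def at_wavelength(self, target_nm: float) -> pd.Series:
        i = self.channel_index(target_nm)
        return pd.Series(
            self.values[i], index=pd.Index(self.times, name="time_min"),
            name=f"{self.wavelengths[i]:.1f}nm",
        )


@dataclass(frozen=True)
class FluorescenceBand:
    """Chlorophyll-fluorescence waveband, inclusive at both edges."""

    lo: float = 669.8
    hi: float = 760.7

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band lo ({self.lo}) must be < hi ({self.hi})")

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.lo) & (wavelengths <= self.hi)


@dataclass(frozen=True)
class IndexWavelengths:
    """Two-band index wavelengths plus the audited candidate list."""

    lambda_signal: float
    lambda_reference: float
    candidates: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.lambda_signal == self.lambda_reference:
            raise ValueError("signal and reference wavelengths must differ")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_to_baseline(series: SpectrumSeries) -> NormalizedSpectrumSeries:
    """Divide every scan by the t = 0 scan, wavelength by wavelength."""
    baseline = series.values[:, 0]
    bad = np.nonzero(baseline <= 0)[0]
    if bad.size:
        raise ValueError(
            f"baseline value <= 0 at {series.wavelengths[bad[0]]:.1f} nm"
        )
    values = series.values / baseline[:, None]
    values[:, 0] = 1.0  # x/x is 1 exactly, but guard fp edge cases anyway
    return NormalizedSpectrumSeries(
        wavelengths=series.wavelengths,
        times=series.times,
        values=values,
        replication_id=series.replication_id,
    )


def compute_narfs(
    norm: NormalizedSpectrumSeries, band: FluorescenceBand | None = None
) -> pd.Series:
    """Normalized average reflectance in the fluorescence spectrum.

    Unweighted mean of the normalized values over all grid channels inside
    the band (edges inclusive); equals exactly 1 at t = 0.
    """
    band = band or FluorescenceBand()
    mask = band.mask(norm.wavelengths)
    n_in = int(mask.sum())
    if n_in < 2:
        raise ValueError(
            f"band {band.lo}-{band.hi} nm overlaps only {n_in} grid channels "
            "(need >= 2)"
        )
    values = norm.values[mask].mean(axis=0)
    return pd.Series(
        values, index=pd.Index(norm.times, name="time_min"), name="nARFS"
    )


def wavelength_variability(
    norm: NormalizedSpectrumSeries, min_timepoints: int = 3
) -> pd.Series:
    """Sample standard deviation of the normalized series per wavelength.

    High values flag channels that responded to the treatment (fluorescence
    growth); the flattest channel is the natural reference for a two-band
    index.
    """
    if norm.times.size < min_timepoints:
        raise ValueError(
            f"need at least {min_timepoints} timepoints, got {norm.times.size}"
        )
    sd = norm.values.std(axis=1, ddof=1)
    return pd.Series(
        sd, index=pd.Index(norm.wavelengths, name="wavelength_nm"),
        name="sd_normalized",
    )


def select_index_wavelengths(
    variability: pd.Series,
    norm: NormalizedSpectrumSeries,
    phi_psii: np.ndarray | pd.Series,
    threshold_quantile: float = 0.90,
) -> IndexWavelengths:
    """Choose the two-band index wavelengths from the variability curve.

    Candidate signal channels are local maxima of the variability curve above
    the given quantile of the whole curve; among them the channel whose
    normalized time series has the largest |Pearson r| against the PSII yield
    becomes the signal band.  The reference band is the global variability
    minimum (the channel least responsive to the treatment).
    """
    sd = np.asarray(variability.values, dtype=float)
    wl = np.asarray(variability.index.values, dtype=float)
    if wl.size != norm.wavelengths.size or not np.allclose(wl, norm.wavelengths):
        raise ValueError("variability and normalized series use different grids")
    phi = np.asarray(phi_psii, dtype=float)
    if phi.size != norm.times.size:
        raise ValueError(
            f"phi_psii has {phi.size} values but the series has "
            f"{norm.times.size} timepoints"
        )

    threshold = float(np.quantile(sd, threshold_quantile))
    peaks, _ = find_peaks(sd)
    candidates = [int(p) for p in peaks if sd[p] >= threshold]
    if not candidates:
        raise ValueError(
            "no variability local maximum above the "
            f"{threshold_quantile:.0%} quantile; lower threshold_quantile"
        )

    if len(candidates) == 1:
        signal_idx = candidates[0]
    else:
        scores = [abs(pearsonr(norm.values[i], phi)[0]) for i in candidates]
        signal_idx = candidates[int(np.argmax(scores))]

    ref_idx = int(np.argmin(sd))
    if ref_idx == signal_idx:  # degenerate flat curve; pick next-flattest
        order = np.argsort(sd)
        ref_idx = int(order[1])
    return IndexWavelengths(
        lambda_signal=float(wl[signal_idx]),
        lambda_reference=float(wl[ref_idx]),
        candidates=tuple((float(wl[i]), float(sd[i])) for i in candidates),
    )


def compute_fbsi(series: SpectrumSeries, idx: IndexWavelengths) -> pd.Series:
    """Fluorescence-based stress index per timepoint.

    FBSI(t) = (R_signal - R_reference)/(R_signal + R_reference) on the raw
    (un-normalized) measurements, as a two-band field sensor would see them;
    strictly inside (-1, 1) for positive readings.
    """
    s = series.values[series.channel_index(idx.lambda_signal)]
    r = series.values[series.channel_index(idx.lambda_reference)]
    denom = s + r
    if np.any(denom <= 0):
        raise ValueError("FBSI denominator (R_signal + R_reference) must be > 0")
    return pd.Series(
        (s - r) / denom, index=pd.Index(series.times, name="time_min"),
        name="FBSI",
    )


# ---------------------------------------------------------------------------
# I/O: wide CSV (wavelength_nm, t0, t15, ...)
# ---------------------------------------------------------------------------

def write_spectrum_csv(series: SpectrumSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        series.values,
        columns=[f"t{t:g}" for t in series.times],
    )
    df.insert(0, "wavelength_nm", series.wavelengths)
    df.to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, replication_id: str = "R1") -> SpectrumSeries:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing 'wavelength_nm' column")
    tcols = [c for c in df.columns if c.startswith("t") and c != "wavelength_nm"]
    try:
        times = np.array([float(c[1:]) for c in tcols])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed time column name") from exc
    order = np.argsort(times)
    return SpectrumSeries(
        wavelengths=df["wavelength_nm"].to_numpy(),
        times=times[order],
        values=df[tcols].to_numpy()[:, order],
        replication_id=replication_id,
    )
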