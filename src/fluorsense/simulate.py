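"""Mechanistic synthetic data for the chlorophyll-fluorescence pipeline.

Three coupled generators emulate one herbicide-stress replication:

* a PSII quantum-yield time course (logistic decline after an onset lag),
* a reflectance/fluorescence spectrum series on a 450-770 nm grid, where
  Gaussian emission peaks at 680 and 740 nm, shaped by within-leaf
  re-absorption, grow on top of a static leaf-reflectance baseline as
  photochemistry fails,
* an 8-bit fluorescence image stack in which damage spreads from the
  herbicide entry point vein-first (along the vein network, then across
  the lamina) and brightens pixels as the local fluorescence yield rises,

plus a PAM record stream (Fs, Fm') consistent with the yield time course,
and a separate dark NPQ-relaxation experiment.

All randomness flows from ``config.seed`` through fixed per-generator
substreams, so runs are exactly reproducible and adding one generator never
perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .imaging import ROI, ImageStack
from .spectral import SpectrumSeries

__all__ = [
    "EnergyPartition",
    "fluorescence_yield",
    "relaxation_partition",
    "simulate_phipsii_timecourse",
    "simulate_reflectance_series",
    "simulate_pam_records",
    "simulate_cfi_stack",
    "simulate_npq_relaxation",
    "StackGroundTruth",
    "RelaxationRun",
    "AtrazineRun",
    "simulate_atrazine_run",
]

# fixed substream ids (counter-based: SeedSequence([seed, stream]))
_STREAM_SPECTRA = 1
_STREAM_IMAGE = 2
_STREAM_PAM = 3
_STREAM_RELAX_IMAGE = 4
_STREAM_RELAX_PAM = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# energy partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyPartition:
    """Fate of absorbed photon energy: photochemistry, heat, fluorescence.

    The three quantum yields are exhaustive and mutually exclusive, so they
    sum to one.
    """

    phi_psii: float
    phi_heat: float
    phi_f: float

    def __post_init__(self) -> None:
        for name in ("phi_psii", "phi_heat", "phi_f"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.phi_psii + self.phi_heat + self.phi_f - 1.0) > 1e-12:
            raise ValueError("quantum yields must sum to 1")


def fluorescence_yield(phi_psii: float, k_f: float) -> EnergyPartition:
    """Partition the non-photochemical share of absorbed energy.

    A fixed fraction ``k_f`` of the energy not used for photochemistry is
    re-emitted as fluorescence; the remainder is dissipated as heat.  This is
    the steady-light regime of the atrazine time course, where the heat /
    fluorescence branching ratio is assumed constant.
    """
    if not (0.0 <= phi_psii <= 1.0):
        raise ValueError(f"phi_psii={phi_psii} outside [0, 1]")
    if not (0.0 < k_f < 1.0):
        raise ValueError(f"k_f={k_f} outside (0, 1)")
    rest = 1.0 - phi_psii
    phi_f = k_f * rest
    phi_heat = rest - phi_f
    return EnergyPartition(phi_psii=phi_psii, phi_heat=phi_heat, phi_f=phi_f)


def relaxation_partition(npq: float, k_f: float, k_p: float) -> EnergyPartition:
    """Energy partition in darkness with an active NPQ quencher.

    Competing first-order rates: photochemistry ``k_p`` (open centres),
    basal non-photochemical decay normalised to 1 (fluorescence fraction
    ``k_f``), and a Stern-Volmer quencher of strength ``npq`` so that
    Fm/Fm' = 1 + NPQ exactly.
    """
    if npq < 0:
        raise ValueError(f"npq={npq} must be >= 0")
    denom = (1.0 + npq) + k_p
    phi_psii = k_p / denom
    phi_f = k_f / denom
    phi_heat = 1.0 - phi_psii - phi_f
    return EnergyPartition(phi_psii=phi_psii, phi_heat=phi_heat, phi_f=phi_f)


# ---------------------------------------------------------------------------
# PSII yield kinetics
# ---------------------------------------------------------------------------

def _phi_of_t(t: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Logistic decline: stable near phi0, midpoint at the lag, floor phi_min."""
    z = (np.asarray(t, dtype=float) - cfg.lag_min) / cfg.tau_min
    return cfg.phi_min + (cfg.phi0 - cfg.phi_min) / (1.0 + np.exp(z))


def _damage_of_t(t: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Damaged fraction c(t) in [0, 1]; phi = phi0*(1-c) + phi_min*c."""
    z = (np.asarray(t, dtype=float) - cfg.lag_min) / cfg.tau_min
    return 1.0 / (1.0 + np.exp(-z))


def simulate_phipsii_timecourse(config: SimulationConfig) -> pd.Series:
    """Noise-free whole-leaf PSII quantum yield at each scan time.

    Returns a series indexed by ``time_min``; the value at the lag time is
    exactly midway between ``phi0`` and ``phi_min``.
    """
    t = config.times()
    phi = _phi_of_t(t, config)
    # enforce the exact logistic midpoint at t == lag (guards fp drift)
    at_lag = np.isclose(t, config.lag_min)
    phi[at_lag] = config.phi_min + (config.phi0 - config.phi_min) / 2.0
    return pd.Series(phi, index=pd.Index(t, name="time_min"), name="phi_psii")


# ---------------------------------------------------------------------------
# reflectance / fluorescence spectra
# ---------------------------------------------------------------------------

def _baseline_spectrum(wl: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Static leaf reflectance: floor + green peak + red-edge logistic rise."""
    b = cfg.baseline
    green = b.green_amplitude * np.exp(
        -0.5 * ((wl - b.green_center_nm) / b.green_sigma_nm) ** 2
    )
    edge = b.nir_plateau / (1.0 + np.exp(-(wl - b.edge_center_nm) / b.edge_width_nm))
    return b.floor + green + edge


def _edge_component(wl: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    b = cfg.baseline
    return b.nir_plateau / (1.0 + np.exp(-(wl - b.edge_center_nm) / b.edge_width_nm))


def _absorptance(wl: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Pigment-absorption proxy: 1 - R(lambda)/max R, in [0, 1]."""
    base = _baseline_spectrum(wl, cfg)
    return 1.0 - base / base.max()


def _emission_spectrum(wl: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Observed emission shape per unit fluorescence yield.

    Two Gaussian bands (chlorophyll-a red and far-red emission) attenuated by
    an escape probability exp(-kappa * absorptance): re-absorption strongly
    quenches the 680 nm band inside the leaf while the far-red band escapes
    nearly unattenuated.
    """
    shape = np.zeros_like(wl, dtype=float)
    for pk in (cfg.peak680, cfg.peak740):
        shape += pk.amplitude * np.exp(-0.5 * ((wl - pk.center_nm) / pk.sigma_nm) ** 2)
    escape = np.exp(-cfg.baseline.reabsorption * _absorptance(wl, cfg))
    return shape * escape


def simulate_reflectance_series(
    config: SimulationConfig, replication_id: str = "R1"
) -> SpectrumSeries:
    """Spectrometer scans R(lambda, t) for one replication.

    R = baseline(lambda, t) * (1 + noise) + phi_f(t) * emission(lambda), where
    the baseline carries two slow deterministic terms: a mild damage-coupled
    reflectance rise in absorbing regions (pigment loss) and, if enabled, the
    small early red-edge transient.
    """
    wl = config.grid.values()
    t = config.times()
    rng = _rng(config.seed, _STREAM_SPECTRA)

    phi = _phi_of_t(t, config)
    c = _damage_of_t(t, config)
    phi_f = config.k_f * (1.0 - phi)

    static = _baseline_spectrum(wl, config)[:, None]           # (wl, 1)
    edge = _edge_component(wl, config)[:, None]
    alpha = _absorptance(wl, config)[:, None]
    bleach = 1.0 + config.baseline.bleach_fraction * alpha * c[None, :]
    dip = config.dip.factor(t)[None, :]                        # (1, t)
    baseline_t = (static - edge + edge * dip) * bleach         # (wl, t)

    emission = _emission_spectrum(wl, config)[:, None] * phi_f[None, :]

    noise = rng.normal(0.0, config.noise.spectral_cv, size=baseline_t.shape) \
        if config.noise.spectral_cv > 0 else 0.0
    values = baseline_t * (1.0 + noise) + emission
    values = np.maximum(values, 1e-9)
    return SpectrumSeries(
        wavelengths=wl, times=t, values=values, replication_id=replication_id
    )


# ---------------------------------------------------------------------------
# PAM records (atrazine time course)
# ---------------------------------------------------------------------------

def simulate_pam_records(
    config: SimulationConfig, replication_id: str = "R1"
) -> pd.DataFrame:
    """Fluorometer stream (time_min, Fs, Fm_prime, Fm) under actinic light.

    Fm' is held at the instrument's light-adapted level; Fs rises toward Fm'
    as the herbicide closes PSII centres, so (Fm' - Fs)/Fm' recovers the
    simulated yield.  Fm (dark-adapted) is not measured in this protocol.
    """
    t = config.times()
    phi = _phi_of_t(t, config)
    rng = _rng(config.seed, _STREAM_PAM)
    fm_prime = np.full_like(phi, 2500.0)
    fs = fm_prime * (1.0 - phi)
    if config.noise.pam_sd > 0:
        fs = fs * (1.0 + rng.normal(0.0, config.noise.pam_sd, size=fs.shape))
        fm_prime = fm_prime * (
            1.0 + rng.normal(0.0, config.noise.pam_sd, size=fm_prime.shape)
        )
    fs = np.clip(fs, 1.0, None)
    fm_prime = np.maximum(fm_prime, fs)  # instrument never reports Fm' < Fs here
    return pd.DataFrame(
        {
            "time_min": t,
            "Fs": fs,
            "Fm_prime": fm_prime,
            "Fm": np.nan,
            "replication_id": replication_id,
        }
    )


# ---------------------------------------------------------------------------
# fluorescence image stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackGroundTruth:
    """Simulator-internal state for one image stack.

    ``distance_map`` is the vein-network travel distance (px) from the
    herbicide entry point; ``damage`` holds c(x, y, t) in [0, 1] per frame.
    ``suggested_roi`` marks where a fluorometer probe would sit (on the
    midvein near the entry point), matching where the other instruments read.
    """

    leaf_mask: np.ndarray
    distance_map: np.ndarray
    entry_point: tuple[int, int]
    vein_points: np.ndarray       # (n, 2) row/col samples along the veins
    vein_distance: np.ndarray     # (n,) along-network distance of each sample
    damage: np.ndarray            # (t, rows, cols) float32
    suggested_roi: ROI


def _vein_network(cfg: SimulationConfig) -> tuple[
    np.ndarray, np.ndarray, tuple[int, int], tuple[float, float], tuple[int, int]
]:
    """Sampled vein polylines with along-network distances from the entry.

    One midvein along the leaf's long axis plus ``n_secondary`` pairs of
    straight secondary veins branching toward the margin.  Returns
    (points, distances, entry_point, semi_axes, centre).
    """
    rows, cols = cfg.imaging.shape
    cr, cc = rows / 2.0, cols / 2.0
    a_r = 0.36 * rows   # semi-axis across the lamina
    a_c = 0.42 * cols   # semi-axis along the midvein
    step = 2.0

    entry = (int(round(cr)), int(round(cc - a_c + 4)))
    tip_col = cc + a_c - 4

    pts: list[tuple[float, float]] = []
    dist: list[float] = []

    # midvein: straight line from entry to tip
    n_mid = max(int(math.ceil((tip_col - entry[1]) / step)), 2)
    mid_cols = np.linspace(entry[1], tip_col, n_mid)
    for col in mid_cols:
        pts.append((cr, col))
        dist.append(col - entry[1])

    # secondary veins branch off the midvein at an angle toward the margin
    n_sec = cfg.imaging.n_secondary
    if n_sec > 0:
        branch_cols = np.linspace(entry[1] + 0.2 * (tip_col - entry[1]),
                                  entry[1] + 0.85 * (tip_col - entry[1]), n_sec)
        for bc in branch_cols:
            d0 = bc - entry[1]
            # lamina half-height at this column (ellipse cross-section)
            x = (bc - cc) / a_c
            half = a_r * math.sqrt(max(1.0 - x * x, 0.0))
            length = 0.8 * half
            n_pts = max(int(math.ceil(length / step)), 2)
            for sign in (-1.0, 1.0):
                for s in np.linspace(0.0, length, n_pts)[1:]:
                    # veins sweep toward the tip at ~40 degrees off the midvein
                    r = cr + sign * s * math.sin(math.radians(70.0))
                    col = bc + s * math.cos(math.radians(70.0))
                    pts.append((r, col))
                    dist.append(d0 + s)

    return (
        np.asarray(pts, dtype=float),
        np.asarray(dist, dtype=float),
        entry,
        (a_r, a_c),
        (int(round(cr)), int(round(cc))),
    )


def _illumination_field(
    shape: tuple[int, int], vignette: float, texture: float
) -> np.ndarray:
    """Fixed multiplicative scene nonuniformity.

    A gentle diagonal illumination gradient plus a fine-grained leaf-surface /
    photo-response pattern.  Both are deterministic functions of pixel
    position only (properties of the rig, not of a run), so the noise-free
    structure is identical for every seed.
    """
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    grad = (y / max(rows - 1, 1) - 0.5) + (x / max(cols - 1, 1) - 0.5)
    tex = np.sin(2.1 * y + 0.7 * x) * np.sin(1.3 * x - 0.5 * y)
    return 1.0 + vignette * grad / 2.0 + texture * tex


def _distance_map(
    cfg: SimulationConfig,
    leaf_mask: np.ndarray,
    vein_pts: np.ndarray,
    vein_dist: np.ndarray,
) -> np.ndarray:
    """Travel distance: min over vein samples of (along-vein distance +
    lamina_factor * Euclidean hop).

    The herbicide rides the transpiration stream quickly through the veins
    and then crosses lamina tissue ``lamina_factor`` times slower, so the
    hop off the network is penalised.  Vectorised in pixel chunks to bound
    memory; background pixels get +inf.
    """
    rows, cols = cfg.imaging.shape
    rr, cc = np.nonzero(leaf_mask)
    coords = np.stack([rr, cc], axis=1).astype(float)
    out = np.full((rows, cols), np.inf)
    chunk = 40000
    for i in range(0, coords.shape[0], chunk):
        block = coords[i : i + chunk]
        d2 = (
            (block[:, None, 0] - vein_pts[None, :, 0]) ** 2
            + (block[:, None, 1] - vein_pts[None, :, 1]) ** 2
        )
        total = cfg.imaging.lamina_factor * np.sqrt(d2) + vein_dist[None, :]
        best = total.min(axis=1)
        out[rr[i : i + chunk], cc[i : i + chunk]] = best
    return out


def simulate_cfi_stack(
    config: SimulationConfig, replication_id: str = "R1"
) -> tuple[ImageStack, StackGroundTruth]:
    """Time-lapse 8-bit fluorescence frames with vein-first damage spread.

    The damage front leaves the entry point at ``vein_speed`` px/min along
    the vein network and then diffuses across the lamina; local PSII yield
    interpolates between healthy and fully damaged, and the pixel value is
    an affine map of the local fluorescence yield plus camera noise,
    quantised to the 0-255 grey scale.
    """
    rows, cols = config.imaging.shape
    vein_pts, vein_dist, entry, (a_r, a_c), (cr, cc) = _vein_network(config)

    y, x = np.mgrid[0:rows, 0:cols]
    leaf_mask = ((y - rows / 2.0) / a_r) ** 2 + ((x - cols / 2.0) / a_c) ** 2 <= 1.0
    dmap = _distance_map(config, leaf_mask, vein_pts, vein_dist)

    t = config.times()
    rng = _rng(config.seed, _STREAM_IMAGE)
    im = config.imaging

    arrival = dmap / im.vein_speed  # minutes for the front to reach each pixel
    frames = np.empty((t.size, rows, cols), dtype=np.uint8)
    damage = np.zeros((t.size, rows, cols), dtype=np.float32)
    bg = np.full((rows, cols), im.background)
    illum = _illumination_field((rows, cols), im.vignette, im.texture)

    for k, tk in enumerate(t):
        with np.errstate(over="ignore"):
            c_local = 1.0 / (1.0 + np.exp(-((tk - config.lag_min - arrival)
                                            / config.tau_min)))
        c_local = np.where(leaf_mask, c_local, 0.0)
        phi_local = config.phi0 * (1.0 - c_local) + config.phi_min * c_local
        phi_f_local = config.k_f * (1.0 - phi_local)
        signal = np.where(
            leaf_mask, (im.offset + im.gain * phi_f_local) * illum, bg
        )
        if config.noise.image_sd > 0:
            signal = signal + rng.normal(0.0, config.noise.image_sd,
                                         size=signal.shape)
        frames[k] = np.clip(np.rint(signal), 0, 255).astype(np.uint8)
        damage[k] = c_local.astype(np.float32)

    # probe-site ROI: centred on the midvein, just downstream of the entry
    side = min(50, rows // 4, cols // 4)
    roi_cc = entry[1] + max(3 * side // 2, 40)
    roi = ROI(
        row0=int(cr - side // 2),
        col0=int(min(roi_cc, cols - side - 1)),
        height=side,
        width=side,
    )

    stack = ImageStack(frames=frames, times=t)
    truth = StackGroundTruth(
        leaf_mask=leaf_mask,
        distance_map=dmap,
        entry_point=entry,
        vein_points=vein_pts,
        vein_distance=vein_dist,
        damage=damage,
        suggested_roi=roi,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# dark NPQ relaxation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationRun:
    """One dark-relaxation experiment on a shared clock."""

    records: pd.DataFrame          # time_min, Fs, Fm_prime, Fm
    stack: ImageStack
    npq_true: pd.Series            # ground-truth NPQ(t)
    phi_psii_true: pd.Series
    phi_f_true: pd.Series
    leaf_mask: np.ndarray
    suggested_roi: ROI


def simulate_npq_relaxation(
    config: SimulationConfig, replication_id: str = "R1"
) -> RelaxationRun:
    """15-min dark period after light exposure: NPQ decays, fluorescence rises.

    NPQ(t) = NPQ0 exp(-t/tau); the competing-rates partition then yields a
    rising PSII quantum yield and a rising fluorescence yield (Fo'-level
    emission un-quenching), imaged as a uniformly brightening leaf.
    """
    r = config.relaxation
    t = config.relaxation_times()
    npq = r.npq0 * np.exp(-t / r.tau_npq_min)

    parts = [relaxation_partition(n, config.k_f, r.k_p) for n in npq]
    phi = np.array([p.phi_psii for p in parts])
    phi_f = np.array([p.phi_f for p in parts])

    # PAM stream: Stern-Volmer Fm' and kinetic Fs, so derived NPQ and PhiPSII
    # round-trip exactly in the noise-free case.
    fm = r.f_scale * config.k_f  # dark-adapted maximum (NPQ = 0)
    fm_prime = fm / (1.0 + npq)
    fs = r.f_scale * config.k_f / ((1.0 + npq) + r.k_p)
    rng = _rng(config.seed, _STREAM_RELAX_PAM)
    if config.noise.pam_sd > 0:
        fs = fs * (1.0 + rng.normal(0.0, config.noise.pam_sd, size=fs.shape))
        fm_prime = fm_prime * (
            1.0 + rng.normal(0.0, config.noise.pam_sd, size=fm_prime.shape)
        )
        fm_prime = np.maximum(fm_prime, fs)
    records = pd.DataFrame(
        {
            "time_min": t,
            "Fs": fs,
            "Fm_prime": fm_prime,
            "Fm": np.full_like(fs, fm),
            "replication_id": replication_id,
        }
    )

    rows, cols = config.imaging.shape
    y, x = np.mgrid[0:rows, 0:cols]
    a_r, a_c = 0.36 * rows, 0.42 * cols
    leaf_mask = ((y - rows / 2.0) / a_r) ** 2 + ((x - cols / 2.0) / a_c) ** 2 <= 1.0

    img_rng = _rng(config.seed, _STREAM_RELAX_IMAGE)
    frames = np.empty((t.size, rows, cols), dtype=np.uint8)
    illum = _illumination_field((rows, cols), config.imaging.vignette,
                                config.imaging.texture)
    for k in range(t.size):
        signal = np.where(
            leaf_mask, (r.offset + r.gain * phi_f[k]) * illum,
            config.imaging.background,
        )
        if config.noise.image_sd > 0:
            signal = signal + img_rng.normal(
                0.0, config.noise.image_sd, size=signal.shape
            )
        frames[k] = np.clip(np.rint(signal), 0, 255).astype(np.uint8)

    side = min(50, rows // 4, cols // 4)
    roi = ROI(
        row0=rows // 2 - side // 2, col0=cols // 2 - side // 2,
        height=side, width=side,
    )
    idx = pd.Index(t, name="time_min")
    return RelaxationRun(
        records=records,
        stack=ImageStack(frames=frames, times=t),
        npq_true=pd.Series(npq, index=idx, name="npq"),
        phi_psii_true=pd.Series(phi, index=idx, name="phi_psii"),
        phi_f_true=pd.Series(phi_f, index=idx, name="phi_f"),
        leaf_mask=leaf_mask,
        suggested_roi=roi,
    )


# ---------------------------------------------------------------------------
# one full replication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtrazineRun:
    """All three measurement streams for one atrazine replication."""

    replication_id: str
    config: SimulationConfig
    spectra: SpectrumSeries
    stack: ImageStack
    truth: StackGroundTruth
    pam: pd.DataFrame
    phi_psii_true: pd.Series


def simulate_atrazine_run(
    config: SimulationConfig, replication_id: str = "R1"
) -> AtrazineRun:
    """Generate spectra, images and PAM records for one replication."""
    spectra = simulate_reflectance_series(config, replication_id)
    stack, truth = simulate_cfi_stack(config, replication_id)
    pam = simulate_pam_records(config, replication_id)
    phi = simulate_phipsii_timecourse(config)
    return AtrazineRun(
        replication_id=replication_id,
        config=config,
        spectra=spectra,
        stack=stack,
        truth=truth,
        pam=pam,
        phi_psii_true=phi,
    )
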