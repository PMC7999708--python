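"""Simulation configuration for the synthetic plant-stress generators.

All generator behaviour is controlled by one frozen :class:`SimulationConfig`
object, so a run is fully described by its config plus a seed.  The defaults
encode the atrazine soil-drench study conditions: an 8-h time course sampled
every 15 min (33 scans), a 450-770 nm reflectance grid, PSII quantum yield
starting near 0.75 and collapsing toward 0.05 once the herbicide reaches the
leaf, and a 480x640 8-bit fluorescence camera.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "WavelengthGrid",
    "EmissionPeak",
    "BaselineParams",
    "TransientDip",
    "NoiseSpec",
    "ImagingParams",
    "RelaxationParams",
    "SimulationConfig",
    "paper_preset",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config parameter {name!r}: {msg}")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform spectrometer wavelength grid (nm)."""

    start: float = 450.0
    stop: float = 770.0
    n_channels: int = 256

    def __post_init__(self) -> None:
        _require(self.start < self.stop, "grid", "start must be < stop")
        _require(self.n_channels >= 8, "grid.n_channels", "need at least 8 channels")
        _require(
            self.start <= 450.0 and self.stop >= 770.0,
            "grid",
            "grid must cover 450-770 nm",
        )

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_channels)


@dataclass(frozen=True)
class EmissionPeak:
    """One Gaussian chlorophyll-a emission peak (unit-peak amplitude form)."""

    center_nm: float
    amplitude: float
    sigma_nm: float

    def __post_init__(self) -> None:
        _require(self.amplitude >= 0, "peak.amplitude", "must be >= 0")
        _require(self.sigma_nm > 0, "peak.sigma_nm", "must be > 0")


@dataclass(frozen=True)
class BaselineParams:
    """Static leaf reflectance shape: green peak, red absorption trough, red edge.

    ``reabsorption`` controls how strongly emitted fluorescence is re-absorbed
    before escaping the leaf (optical depth multiplying the absorptance proxy
    1 - R/R_nir); this is what shifts the observed red emission maximum away
    from 680 nm, as in real leaves.  ``bleach_fraction`` is the maximal
    relative reflectance rise in strongly absorbing regions once tissue is
    fully damaged (mild pigment loss late in the time course).
    """

    floor: float = 0.04
    green_center_nm: float = 550.0
    green_amplitude: float = 0.08
    green_sigma_nm: float = 35.0
    edge_center_nm: float = 710.0
    edge_width_nm: float = 15.0
    nir_plateau: float = 0.45
    reabsorption: float = 2.0
    bleach_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("floor", "green_amplitude", "nir_plateau"):
            _require(getattr(self, name) > 0, f"baseline.{name}", "must be > 0")
        _require(self.edge_width_nm > 0, "baseline.edge_width_nm", "must be > 0")
        _require(self.reabsorption >= 0, "baseline.reabsorption", "must be >= 0")
        _require(
            0 <= self.bleach_fraction < 1, "baseline.bleach_fraction", "must be in [0, 1)"
        )


@dataclass(frozen=True)
class TransientDip:
    """Optional small early depression of the red-edge reflectance component.

    Emulates the slight transient drop of in-band reflectance sometimes seen
    in the first hours after herbicide application, before fluorescence
    growth dominates.  Shape: amplitude * (t/peak) * exp(1 - t/peak).
    """

    enabled: bool = False
    amplitude: float = 0.012
    peak_min: float = 80.0

    def __post_init__(self) -> None:
        _require(0 <= self.amplitude < 0.2, "dip.amplitude", "must be in [0, 0.2)")
        _require(self.peak_min > 0, "dip.peak_min", "must be > 0")

    def factor(self, t_min: np.ndarray) -> np.ndarray:
        """Multiplicative depression 1 - delta(t) applied to the red edge."""
        if not self.enabled:
            return np.ones_like(np.asarray(t_min, dtype=float))
        t = np.asarray(t_min, dtype=float)
        x = t / self.peak_min
        return 1.0 - self.amplitude * x * np.exp(1.0 - x)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise magnitudes for the three instruments."""

    spectral_cv: float = 0.005  # multiplicative, per channel and scan
    image_sd: float = 2.0       # additive grey levels per pixel, pre-quantisation
    pam_sd: float = 0.01        # multiplicative, on Fs and Fm'

    def __post_init__(self) -> None:
        for name in ("spectral_cv", "image_sd", "pam_sd"):
            _require(getattr(self, name) >= 0, f"noise.{name}", "must be >= 0")

    def zeroed(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ImagingParams:
    """Fluorescence-camera geometry and radiometry.

    ``gain`` maps fluorescence quantum yield to grey levels; ``offset`` is the
    in-leaf signal floor and ``background`` the non-leaf level.  ``vein_speed``
    is the speed of the damage front along the vein network in px/min;
    ``lamina_factor`` is how much slower the front crosses lamina tissue
    than it travels through the transpiration stream of the veins.
    ``vignette`` is the relative amplitude of the fixed illumination
    nonuniformity across the scene (no LED panel lights a canopy evenly)
    and ``texture`` that of the fine-grained leaf-surface / photo-response
    pattern; both are deterministic properties of the rig, identical across
    runs and seeds.
    """

    shape: tuple[int, int] = (480, 640)
    gain: float = 800.0
    offset: float = 15.0
    background: float = 3.0
    vein_speed: float = 2.0
    n_secondary: int = 6
    lamina_factor: float = 4.0
    vignette: float = 0.10
    texture: float = 0.03

    def __post_init__(self) -> None:
        _require(
            len(self.shape) == 2 and min(self.shape) >= 64,
            "imaging.shape",
            "frame must be at least 64x64 pixels to hold the leaf geometry",
        )
        _require(self.gain > 0, "imaging.gain", "must be > 0")
        _require(self.vein_speed > 0, "imaging.vein_speed", "must be > 0")
        _require(self.n_secondary >= 0, "imaging.n_secondary", "must be >= 0")
        _require(self.lamina_factor >= 1, "imaging.lamina_factor", "must be >= 1")
        _require(0 <= self.vignette < 1, "imaging.vignette", "must be in [0, 1)")
        _require(0 <= self.texture < 1, "imaging.texture", "must be in [0, 1)")


@dataclass(frozen=True)
class RelaxationParams:
    """Dark NPQ-relaxation experiment (15 min after a light period).

    NPQ decays exponentially with time constant ``tau_npq_min``; steady and
    saturating-pulse fluorescence follow a competing-rates model in which the
    basal non-photochemical rate is normalised to 1, photochemistry runs at
    rate ``k_p`` (open centres in darkness), and the NPQ quencher obeys
    Stern-Volmer quenching of Fm.
    """

    npq0: float = 2.4
    tau_npq_min: float = 50.0
    duration_min: float = 15.0
    interval_min: float = 1.0
    k_p: float = 4.0
    gain: float = 4000.0
    offset: float = 2.0
    f_scale: float = 30000.0

    def __post_init__(self) -> None:
        _require(self.npq0 >= 0, "relaxation.npq0", "NPQ0 must be >= 0")
        _require(self.tau_npq_min > 0, "relaxation.tau_npq_min", "must be > 0")
        _require(self.duration_min > 0, "relaxation.duration_min", "must be > 0")
        _require(
            0 < self.interval_min <= self.duration_min,
            "relaxation.interval_min",
            "must be in (0, duration]",
        )
        _require(self.k_p > 0, "relaxation.k_p", "must be > 0")
        _require(self.f_scale > 0, "relaxation.f_scale", "must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    duration_min: float = 480.0
    interval_min: float = 15.0
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    phi0: float = 0.75
    phi_min: float = 0.05
    lag_min: float = 150.0
    tau_min: float = 60.0
    k_f: float = 0.10
    peak680: EmissionPeak = field(
        default_factory=lambda: EmissionPeak(680.0, 1.0, 10.0)
    )
    peak740: EmissionPeak = field(
        default_factory=lambda: EmissionPeak(740.0, 2.0, 18.0)
    )
    baseline: BaselineParams = field(default_factory=BaselineParams)
    dip: TransientDip = field(default_factory=TransientDip)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    relaxation: RelaxationParams = field(default_factory=RelaxationParams)
    n_replications: int = 3

    def __post_init__(self) -> None:
        _require(self.duration_min > 0, "duration_min", "must be > 0")
        _require(self.interval_min > 0, "interval_min", "must be > 0")
        n_steps = self.duration_min / self.interval_min
        _require(
            abs(n_steps - round(n_steps)) < 1e-9,
            "interval_min",
            "interval must divide the duration",
        )
        _require(0 < self.phi_min < self.phi0 < 1, "phi0/phi_min",
                 "need 0 < phi_min < phi0 < 1")
        _require(0 < self.k_f < 1, "k_f", "must be in (0, 1)")
        _require(self.lag_min >= 0, "lag_min", "must be >= 0")
        _require(self.tau_min > 0, "tau_min", "must be > 0")
        _require(self.n_replications >= 1, "n_replications", "must be >= 1")

    # -- derived ----------------------------------------------------------
    def times(self) -> np.ndarray:
        """Scan times in minutes: 0, interval, ..., duration (inclusive)."""
        n = int(round(self.duration_min / self.interval_min))
        return np.arange(n + 1) * self.interval_min

    def relaxation_times(self) -> np.ndarray:
        r = self.relaxation
        n = int(round(r.duration_min / r.interval_min))
        return np.arange(n + 1) * r.interval_min

    # -- variants ---------------------------------------------------------
    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def without_noise(self) -> "SimulationConfig":
        return self.replace(noise=self.noise.zeroed())

    def with_seed(self, seed: int) -> "SimulationConfig":
        return self.replace(seed=int(seed))

    # -- (de)serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        nested = {
            "grid": WavelengthGrid,
            "peak680": EmissionPeak,
            "peak740": EmissionPeak,
            "baseline": BaselineParams,
            "dip": TransientDip,
            "noise": NoiseSpec,
            "imaging": ImagingParams,
            "relaxation": RelaxationParams,
        }
        for key, typ in nested.items():
            if key in d and isinstance(d[key], dict):
                if typ is ImagingParams and "shape" in d[key]:
                    d[key]["shape"] = tuple(d[key]["shape"])
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "imaging" in raw and isinstance(raw["imaging"], dict):
            shape = raw["imaging"].get("shape")
            if shape is not None:
                raw["imaging"]["shape"] = tuple(shape)
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["imaging"]["shape"] = list(d["imaging"]["shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def paper_preset(seed: int = 1) -> SimulationConfig:
    """Study-faithful configuration: default kinetics, optics and noise, with
    the early red-edge transient enabled so the in-band average shows its
    slight initial dip before the fluorescence-driven rise."""
    return SimulationConfig(seed=seed, dip=TransientDip(enabled=True))
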