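"""Stream alignment, per-replication correlation analysis, and the pipeline.

The study design interleaves three instruments on a shared 15-min clock:
reflectometer scans (giving nARFS and the FBSI), the fluorescence camera
(giving ROI pixel intensity), and the PAM fluorometer (giving PhiPSII and,
in the relaxation study, NPQ).  Rows are matched by timestamp within a small
tolerance, and each replication is analysed separately with ordinary
least-squares / Pearson correlation per variable pair -- replications are
never pooled, because absolute fluorescence levels differ plant to plant and
the method is deliberately qualitative.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import linregress

from . import fluorometry, imaging, simulate, spectral
from .config import SimulationConfig, paper_preset

__all__ = [
    "TimeCourseTable",
    "CorrelationResult",
    "align_timepoints",
    "pairwise_correlations",
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "DEFAULT_PAIRS",
    "RELAXATION_PAIRS",
]

logger = logging.getLogger("fluorsense")

DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("pixel_mean", "phi_psii"),
    ("pixel_mean", "nARFS"),
    ("nARFS", "phi_psii"),
    ("FBSI", "phi_psii"),
)
RELAXATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("pixel_mean", "npq"),
    ("pixel_mean", "phi_psii"),
)


@dataclass(frozen=True)
class TimeCourseTable:
    """Per-timepoint alignment of all measurement streams, one replication."""

    replication_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.data["time_min"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("aligned times must be strictly increasing")
        if pd.Index(t).has_duplicates:
            raise ValueError("duplicated timepoints in aligned table")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    replication_id: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


def align_timepoints(
    spectra_derived: pd.DataFrame,
    image_derived: pd.DataFrame,
    pam_derived: pd.DataFrame,
    tolerance_min: float = 5.0,
    replication_id: str = "R1",
) -> TimeCourseTable:
    """Match the three streams by timestamp (nearest, strictly within tolerance).

    The spectral clock is the reference; unmatched timepoints are dropped
    (with a logged count).  Raises if fewer than 3 complete rows remain.
    """
    streams = {
        "spectra": spectra_derived,
        "images": image_derived,
        "pam": pam_derived,
    }
    for name, df in streams.items():
        if "time_min" not in df.columns:
            raise ValueError(f"{name} stream lacks a 'time_min' column")
        if len(df) < 3:
            raise ValueError(f"{name} stream has fewer than 3 timepoints")

    merged = spectra_derived.sort_values("time_min").reset_index(drop=True).copy()
    base_t = merged["time_min"].to_numpy(dtype=float)
    for name in ("images", "pam"):
        other = streams[name].sort_values("time_min").reset_index(drop=True)
        ot = other["time_min"].to_numpy(dtype=float)
        right = np.searchsorted(ot, base_t)
        left = np.clip(right - 1, 0, ot.size - 1)
        right = np.clip(right, 0, ot.size - 1)
        nearest = np.where(
            np.abs(ot[left] - base_t) <= np.abs(ot[right] - base_t), left, right
        )
        matched = np.abs(ot[nearest] - base_t) < tolerance_min  # strict
        if not matched.any():
            raise ValueError(
                f"{name} stream: zero timepoints matched within "
                f"{tolerance_min} min of the spectral clock"
            )
        for col in other.columns:
            if col == "time_min":
                continue
            out_col = col if col not in merged.columns else f"{col}_{name}"
            vals = other[col].to_numpy()[nearest]
            merged[out_col] = pd.Series(vals).where(matched, other=np.nan)
    # columns that are entirely absent (e.g. NPQ without a dark Fm) are not
    # "requested" and must not empty the table
    value_cols = [
        c for c in merged.columns
        if c != "time_min" and not merged[c].isna().all()
    ]
    complete = merged.dropna(subset=value_cols)
    dropped = len(merged) - len(complete)
    if dropped:
        logger.info(
            "alignment (%s): dropped %d of %d timepoints outside +/-%g min",
            replication_id, dropped, len(merged), tolerance_min,
        )
    if len(complete) < 3:
        raise ValueError(
            f"only {len(complete)} timepoints matched within "
            f"{tolerance_min} min; need >= 3"
        )
    return TimeCourseTable(
        replication_id=replication_id, data=complete.reset_index(drop=True)
    )


def pairwise_correlations(
    table: TimeCourseTable,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> list[CorrelationResult]:
    """Pearson r, two-sided p (t transform, n-2 df) and OLS line per pair."""
    results = []
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in table.data.columns:
                raise ValueError(f"column {name!r} not in aligned table")
        sub = table.data[[x_name, y_name]].dropna()
        x = sub[x_name].to_numpy(dtype=float)
        y = sub[y_name].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"pair ({x_name}, {y_name}): fewer than 3 rows")
        for name, v in ((x_name, x), (y_name, y)):
            if np.ptp(v) == 0:
                raise ValueError(f"column {name!r} has zero variance")
        fit = linregress(x, y)
        results.append(
            CorrelationResult(
                pair=(x_name, y_name),
                r=float(fit.rvalue),
                p_value=float(fit.pvalue),
                n=int(x.size),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                replication_id=table.replication_id,
            )
        )
    return results


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replication_id": [r.replication_id for r in results],
            "x": [r.pair[0] for r in results],
            "y": [r.pair[1] for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
        }
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run description (``mode='synthetic'`` or ``mode='files'``)."""

    mode: str = "synthetic"
    preset: str = "paper"
    seed: int = 1
    n_replications: int = 3
    out_dir: str = "fluorsense_out"
    tolerance_min: float = 5.0
    threshold_quantile: float = 0.90
    band: tuple[float, float] = (669.8, 760.7)
    roi: tuple[int, int, int, int] | None = None
    include_relaxation: bool = True
    write_plots: bool = True
    simulation: dict[str, Any] = field(default_factory=dict)
    # files mode (single replication)
    spectra_csv: str | None = None
    frames_dir: str | None = None
    pam_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if raw.get("roi") is not None:
            raw["roi"] = tuple(raw["roi"])
        return cls(**raw)


@dataclass(frozen=True)
class ReplicationResult:
    replication_id: str
    table: TimeCourseTable
    correlations: list[CorrelationResult]
    index_wavelengths: spectral.IndexWavelengths
    variability: pd.Series
    narfs: pd.Series
    fbsi: pd.Series
    normalized: spectral.NormalizedSpectrumSeries | None = None


@dataclass(frozen=True)
class ReportBundle:
    out_dir: Path
    replications: list[ReplicationResult]
    relaxation: list[ReplicationResult]
    correlation_table: pd.DataFrame


def _stage(name: str):
    """Decorator-ish context: run fn, log timing, wrap failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2f s", name, dt)
                return False
            raise PipelineStageError(name, exc) from exc
    return _Ctx()


def analyze_replication(
    spectra: spectral.SpectrumSeries,
    stack: imaging.ImageStack,
    pam_table: pd.DataFrame,
    roi: imaging.ROI,
    band: spectral.FluorescenceBand | None = None,
    tolerance_min: float = 5.0,
    threshold_quantile: float = 0.90,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> ReplicationResult:
    """Run the full analysis chain for one replication's three streams."""
    rep = spectra.replication_id
    with _stage("normalize"):
        norm = spectral.normalize_to_baseline(spectra)
    with _stage("narfs"):
        narfs = spectral.compute_narfs(norm, band)
    with _stage("variability"):
        variability = spectral.wavelength_variability(norm)
    with _stage("fluorometry"):
        yields = fluorometry.derive_yields(pam_table)
    with _stage("wavelength-selection"):
        phi_on_spectra_clock = (
            yields.set_index("time_min")["phi_psii"]
            .reindex(pd.Index(norm.times), method="nearest")
            .to_numpy()
        )
        idx = spectral.select_index_wavelengths(
            variability, norm, phi_on_spectra_clock,
            threshold_quantile=threshold_quantile,
        )
    with _stage("fbsi"):
        fbsi = spectral.compute_fbsi(spectra, idx)
    with _stage("roi-intensity"):
        intensity = imaging.intensity_timecourse(stack, roi)
    with _stage("alignment"):
        spectra_stream = pd.DataFrame(
            {"time_min": narfs.index, "nARFS": narfs.values,
             "FBSI": fbsi.values}
        )
        image_stream = intensity.rename(
            columns={"mean_intensity": "pixel_mean", "sd_intensity": "pixel_sd"}
        )
        table = align_timepoints(
            spectra_stream, image_stream, yields,
            tolerance_min=tolerance_min, replication_id=rep,
        )
    with _stage("correlations"):
        usable_pairs = [
            p for p in pairs
            if not table.data[list(p)].isna().any().any()
        ]
        results = pairwise_correlations(table, usable_pairs)
    return ReplicationResult(
        replication_id=rep,
        table=table,
        correlations=results,
        index_wavelengths=idx,
        variability=variability,
        narfs=narfs,
        fbsi=fbsi,
        normalized=norm,
    )


def _relaxation_replication(
    run: simulate.RelaxationRun, replication_id: str, tolerance_min: float
) -> ReplicationResult:
    with _stage("relaxation-analysis"):
        yields = fluorometry.derive_yields(run.records)
        intensity = imaging.intensity_timecourse(run.stack, run.suggested_roi)
        image_stream = intensity.rename(
            columns={"mean_intensity": "pixel_mean", "sd_intensity": "pixel_sd"}
        )
        merged = pd.merge_asof(
            image_stream.sort_values("time_min"),
            yields.sort_values("time_min"),
            on="time_min", direction="nearest", tolerance=tolerance_min,
        ).dropna(subset=["pixel_mean", "phi_psii", "npq"])
        table = TimeCourseTable(
            replication_id=replication_id, data=merged.reset_index(drop=True)
        )
        results = pairwise_correlations(table, RELAXATION_PAIRS)
    empty = pd.Series(dtype=float)
    return ReplicationResult(
        replication_id=replication_id,
        table=table,
        correlations=results,
        index_wavelengths=spectral.IndexWavelengths(741.2, 548.9),
        variability=empty,
        narfs=empty,
        fbsi=empty,
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _simulation_config(pcfg: PipelineConfig, seed: int) -> SimulationConfig:
    if pcfg.preset == "paper":
        base = paper_preset(seed)
    else:
        base = SimulationConfig(seed=seed)
    if pcfg.simulation:
        merged = _deep_merge(base.to_dict(), pcfg.simulation)
        merged["seed"] = seed
        return SimulationConfig.from_dict(merged)
    return base


def atrazine_study_correlations(
    base_seed: int = 1,
    n_replications: int = 3,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Study-preset correlations, one row per replication.

    Simulates replications with seeds ``base_seed .. base_seed+n-1`` under
    the study-faithful preset (or a supplied config), runs the full analysis
    chain with the probe-site ROI, and returns the four headline Pearson
    coefficients per replication: r(pixel, PhiPSII), r(pixel, nARFS),
    r(nARFS, PhiPSII) and r(FBSI, PhiPSII).
    """
    rows = []
    for i in range(n_replications):
        rep_id = f"R{i + 1}"
        cfg = (config or paper_preset(base_seed)).with_seed(base_seed + i)
        run = simulate.simulate_atrazine_run(cfg, rep_id)
        rep = analyze_replication(
            run.spectra, run.stack, run.pam, run.truth.suggested_roi
        )
        by_pair = {r.pair: r for r in rep.correlations}
        rows.append(
            {
                "replication_id": rep_id,
                "seed": base_seed + i,
                "n": len(rep.table),
                "r_pixel_phi": by_pair[("pixel_mean", "phi_psii")].r,
                "r_pixel_narfs": by_pair[("pixel_mean", "nARFS")].r,
                "r_narfs_phi": by_pair[("nARFS", "phi_psii")].r,
                "r_fbsi_phi": by_pair[("FBSI", "phi_psii")].r,
                "signal_nm": rep.index_wavelengths.lambda_signal,
                "reference_nm": rep.index_wavelengths.lambda_reference,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | str | Path) -> ReportBundle:
    """Execute the whole chain and write the report bundle to ``out_dir``.

    Synthetic mode generates ``n_replications`` replications with seeds
    ``seed, seed+1, ...``; files mode analyses one replication from the
    supplied spectra CSV, frame directory and PAM CSV.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    band = spectral.FluorescenceBand(*config.band)

    replications: list[ReplicationResult] = []
    relaxations: list[ReplicationResult] = []

    if config.mode == "synthetic":
        for i in range(config.n_replications):
            rep_id = f"R{i + 1}"
            cfg = _simulation_config(config, config.seed + i)
            with _stage(f"simulate-{rep_id}"):
                run = simulate.simulate_atrazine_run(cfg, rep_id)
            roi = (
                imaging.ROI(*config.roi) if config.roi is not None
                else run.truth.suggested_roi
            )
            rep = analyze_replication(
                run.spectra, run.stack, run.pam, roi, band,
                tolerance_min=config.tolerance_min,
                threshold_quantile=config.threshold_quantile,
            )
            replications.append(rep)
            if config.include_relaxation:
                with _stage(f"simulate-relaxation-{rep_id}"):
                    relax = simulate.simulate_npq_relaxation(cfg, rep_id)
                relaxations.append(
                    _relaxation_replication(relax, rep_id, config.tolerance_min)
                )
    elif config.mode == "files":
        with _stage("load-inputs"):
            for name, p in (("spectra_csv", config.spectra_csv),
                            ("frames_dir", config.frames_dir),
                            ("pam_csv", config.pam_csv)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: missing input {p!r}")
            series = spectral.read_spectrum_csv(config.spectra_csv)
            stack = imaging.read_stack(config.frames_dir)
            pam_table = fluorometry.read_pam_csv(config.pam_csv)
        if config.roi is None:
            raise ValueError("files mode requires an explicit roi")
        rep = analyze_replication(
            series, stack, pam_table, imaging.ROI(*config.roi), band,
            tolerance_min=config.tolerance_min,
            threshold_quantile=config.threshold_quantile,
        )
        replications.append(rep)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")

    with _stage("report"):
        all_results = [r for rep in replications for r in rep.correlations]
        all_results += [r for rep in relaxations for r in rep.correlations]
        corr = correlations_frame(all_results)
        corr.to_csv(out / "correlations.csv", index=False)

        for rep in replications:
            rep.table.data.to_csv(
                out / f"timecourse_{rep.replication_id}.csv", index=False
            )
            rep.variability.to_csv(
                out / f"variability_{rep.replication_id}.csv"
            )
        for rep in relaxations:
            rep.table.data.to_csv(
                out / f"relaxation_{rep.replication_id}.csv", index=False
            )

        summary = {
            "n_replications": len(replications),
            "n_correlations": len(all_results),
            "index_wavelengths": {
                rep.replication_id: {
                    "signal_nm": rep.index_wavelengths.lambda_signal,
                    "reference_nm": rep.index_wavelengths.lambda_reference,
                    "candidates": list(rep.index_wavelengths.candidates),
                }
                for rep in replications
            },
            "correlations": [
                {**dataclasses.asdict(r), "pair": list(r.pair)}
                for r in all_results
            ],
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        if config.write_plots and replications:
            from . import plots  # deferred: pulls in matplotlib
            plots.write_report_plots(out, replications)

    return ReportBundle(
        out_dir=out,
        replications=replications,
        relaxation=relaxations,
        correlation_table=corr,
    )
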