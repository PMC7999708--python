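"""Report figures: spectra fan, variability curve, time courses, scatters."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "plot_spectra_fan",
    "plot_variability",
    "plot_timecourses",
    "plot_scatter_panels",
    "write_report_plots",
]


def plot_spectra_fan(rep, path: str | Path) -> None:
    """Normalized spectra, one line per scan, coloured by elapsed time."""
    norm = rep.normalized
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cmap = plt.get_cmap("viridis")
    tmax = norm.times.max() or 1.0
    for j, t in enumerate(norm.times):
        ax.plot(norm.wavelengths, norm.values[:, j],
                color=cmap(t / tmax), lw=0.8)
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=plt.Normalize(0, tmax))
    fig.colorbar(sm, ax=ax, label="time (min)")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("normalized reflectance / fluorescence")
    ax.set_title(f"Normalized spectra ({rep.replication_id})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_variability(rep, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(rep.variability.index, rep.variability.values, lw=1.2)
    idx = rep.index_wavelengths
    ax.axvline(idx.lambda_signal, color="crimson", ls="--",
               label=f"signal {idx.lambda_signal:.1f} nm")
    ax.axvline(idx.lambda_reference, color="seagreen", ls="--",
               label=f"reference {idx.lambda_reference:.1f} nm")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("SD of normalized series")
    ax.set_title(f"Per-wavelength variability ({rep.replication_id})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_timecourses(reps: Sequence, path: str | Path) -> None:
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    for rep in reps:
        d = rep.table.data
        axes[0].plot(d["time_min"], d["pixel_mean"], marker="o", ms=3,
                     label=rep.replication_id)
        axes[1].plot(d["time_min"], d["phi_psii"], marker="o", ms=3)
        axes[2].plot(d["time_min"], d["nARFS"], marker="o", ms=3)
    axes[0].set_ylabel("pixel intensity")
    axes[1].set_ylabel(r"$\Phi_{PSII}$")
    axes[2].set_ylabel("nARFS")
    axes[2].set_xlabel("time after application (min)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_PANEL_PAIRS = (
    ("pixel_mean", "phi_psii"),
    ("pixel_mean", "nARFS"),
    ("nARFS", "phi_psii"),
    ("FBSI", "phi_psii"),
)
_LABELS = {
    "pixel_mean": "pixel intensity",
    "phi_psii": r"$\Phi_{PSII}$",
    "nARFS": "nARFS",
    "FBSI": "FBSI",
    "npq": "NPQ",
}


def plot_scatter_panels(reps: Sequence, path: str | Path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (xn, yn) in zip(axes.ravel(), _PANEL_PAIRS):
        for rep in reps:
            d = rep.table.data
            if xn in d.columns and yn in d.columns:
                ax.scatter(d[xn], d[yn], s=12, label=rep.replication_id)
        ax.set_xlabel(_LABELS.get(xn, xn))
        ax.set_ylabel(_LABELS.get(yn, yn))
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report_plots(out_dir: str | Path, reps: Sequence) -> None:
    out = Path(out_dir)
    for rep in reps:
        if rep.normalized is not None:
            plot_spectra_fan(rep, out / f"spectra_{rep.replication_id}.png")
            plot_variability(rep, out / f"variability_{rep.replication_id}.png")
    plot_timecourses(reps, out / "timecourses.png")
    plot_scatter_panels(reps, out / "correlation_panels.png")
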