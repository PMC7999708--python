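"""PAM-fluorometry derived parameters: PSII quantum yield and NPQ.

A saturating-pulse measurement pair (steady-state Fs, pulse maximum Fm')
yields the operating PSII quantum yield (Fm' - Fs)/Fm'; with an additional
dark-adapted maximum Fm, non-photochemical quenching is (Fm - Fm')/Fm'.
Physically impossible orderings (Fs > Fm', Fm < Fm') can arise from
instrument noise near saturation, so they are flagged rather than rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PAMRecord",
    "YieldValue",
    "phi_psii",
    "npq",
    "derive_yields",
    "read_pam_csv",
    "write_pam_csv",
]


class YieldValue(NamedTuple):
    """A derived fluorometric parameter plus data-quality flags."""

    value: float
    flags: tuple[str, ...] = ()

    def __float__(self) -> float:  # allows float(phi_psii(rec))
        return self.value


@dataclass(frozen=True)
class PAMRecord:
    """One saturating-pulse measurement.

    Fs: steady-state fluorescence under ambient light; Fm_prime: maximum
    during the pulse; Fm: dark-adapted maximum (optional, needed for NPQ).
    All in instrument units.
    """

    time_min: float
    fs: float
    fm_prime: float
    fm: float | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"Fs must be > 0, got {self.fs}")
        if self.fm is not None and not math.isnan(self.fm) and self.fm <= 0:
            raise ValueError(f"Fm must be > 0, got {self.fm}")

    @property
    def has_fm(self) -> bool:
        return self.fm is not None and not math.isnan(self.fm)

    def quality_flags(self) -> tuple[str, ...]:
        flags: list[str] = []
        if self.fs > self.fm_prime:
            flags.append("Fs>Fm'")
        if self.has_fm and self.fm < self.fm_prime:
            flags.append("Fm<Fm'")
        return tuple(flags)


def phi_psii(record: PAMRecord) -> YieldValue:
    """Operating quantum yield of PSII photochemistry, (Fm' - Fs)/Fm'."""
    if record.fm_prime <= 0:
        raise ValueError(f"Fm' must be > 0, got {record.fm_prime}")
    value = (record.fm_prime - record.fs) / record.fm_prime
    flags = ("Fs>Fm'",) if record.fs > record.fm_prime else ()
    return YieldValue(value, flags)


def npq(record: PAMRecord) -> YieldValue:
    """Non-photochemical quenching, (Fm - Fm')/Fm' (Stern-Volmer form)."""
    if not record.has_fm:
        raise ValueError("NPQ requires the dark-adapted Fm measurement")
    if record.fm_prime <= 0:
        raise ValueError(f"Fm' must be > 0, got {record.fm_prime}")
    value = (record.fm - record.fm_prime) / record.fm_prime
    flags = ("Fm<Fm'",) if record.fm < record.fm_prime else ()
    return YieldValue(value, flags)


def derive_yields(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised derivation over a PAM table (time_min, Fs, Fm_prime[, Fm]).

    Returns time_min, phi_psii, npq (NaN where Fm is absent) and a
    semicolon-joined ``flags`` column.
    """
    for col in ("time_min", "Fs", "Fm_prime"):
        if col not in records.columns:
            raise ValueError(f"PAM table missing column {col!r}")
    out_rows = []
    has_fm_col = "Fm" in records.columns
    for _, row in records.iterrows():
        rec = PAMRecord(
            time_min=float(row["time_min"]),
            fs=float(row["Fs"]),
            fm_prime=float(row["Fm_prime"]),
            fm=float(row["Fm"]) if has_fm_col and pd.notna(row["Fm"]) else None,
        )
        p = phi_psii(rec)
        flags = set(p.flags)
        if rec.has_fm:
            q = npq(rec)
            flags |= set(q.flags)
            npq_val = q.value
        else:
            npq_val = np.nan
        out_rows.append(
            (rec.time_min, p.value, npq_val, ";".join(sorted(flags)))
        )
    return pd.DataFrame(
        out_rows, columns=["time_min", "phi_psii", "npq", "flags"]
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_pam_csv(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("time_min", "Fs", "Fm_prime", "Fm", "replication_id")
            if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_pam_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_min", "Fs", "Fm_prime"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df
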