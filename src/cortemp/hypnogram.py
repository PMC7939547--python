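"""Hypnograms and temperature traces: containers, readers, writers.

A hypnogram is a per-epoch sequence of scored sleep-wake states — wake (W),
NREM sleep (N), and REM sleep (R) — at a fixed epoch duration (4 s by
convention). Recordings are anchored to the light cycle: epoch 0 is assumed
to fall at light onset (Zeitgeber time ZT0) under a 12:12 h light-dark cycle
unless stated otherwise. A temperature trace carries one cortical temperature
value in degrees Celsius per epoch and is paired 1:1 with a hypnogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Hypnogram",
    "TemperatureTrace",
    "read_hypnogram",
    "write_hypnogram",
    "read_temperature",
    "write_temperature",
    "read_recording_spreadsheet",
    "validate_pair",
    "STATES",
]

#: Canonical state alphabet.
STATES = ("W", "N", "R")

# Vendor token alphabet: numeric codes 1/2/3 and letters, case-insensitive.
_BASE_TOKENS = {
    "w": "W", "1": "W",
    "n": "N", "2": "N",
    "r": "R", "3": "R",
}
# Artefact markers appended to a token ("W*", "1a"); artefact-flagged epochs
# keep their underlying state and are retained in all analyses.
_ARTEFACT_SUFFIXES = ("*", "a", "'", "`")


def _map_token(token: str) -> str:
    t = token.strip().lower()
    if t in _BASE_TOKENS:
        return _BASE_TOKENS[t]
    if len(t) > 1 and t[-1] in _ARTEFACT_SUFFIXES and t[:-1] in _BASE_TOKENS:
        return _BASE_TOKENS[t[:-1]]
    raise ValueError(f"unknown state token {token!r}")


@dataclass
class Hypnogram:
    """Per-epoch sleep-wake state sequence.

    Parameters
    ----------
    states
        One label per epoch, each in ``{"W", "N", "R"}`` (vendor tokens such
        as ``"1"`` or ``"w*"`` are accepted and canonicalized).
    epoch_s
        Epoch duration in seconds. The time step used in all model math is
        exactly ``epoch_s / 3600`` hours (4 s -> 1/900 h).
    start_zt_h
        Zeitgeber time (hours after light onset) of the first epoch.
    light_h, dark_h
        Photoperiod lengths in hours.
    sd_intervals
        Optional ``(start_h, end_h)`` sleep-deprivation annotations, in hours
        from recording start. Metadata only; they do not alter computation.
    """

    states: np.ndarray
    epoch_s: float = 4.0
    start_zt_h: float = 0.0
    light_h: float = 12.0
    dark_h: float = 12.0
    sd_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        states = np.asarray(
            [_map_token(s) if s not in STATES else s
             for s in np.asarray(self.states, dtype=object)],
            dtype="<U1",
        )
        if states.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be positive")
        self.states = states
        for lo, hi in self.sd_intervals:
            if not (0 <= lo <= hi <= self.duration_h + 1e-9):
                raise ValueError(
                    f"sd_interval ({lo}, {hi}) outside recording [0, "
                    f"{self.duration_h:.4g}] h"
                )

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def dt_h(self) -> float:
        """Exact epoch duration in hours."""
        return self.epoch_s / 3600.0

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.dt_h

    @property
    def is_active(self) -> np.ndarray:
        """Boolean mask of temperature-raising states (wake or REM sleep)."""
        return (self.states == "W") | (self.states == "R")

    def zt_h(self) -> np.ndarray:
        """Zeitgeber time (h) at the start of every epoch, not wrapped."""
        return self.start_zt_h + np.arange(self.n_epochs) * self.dt_h

    def state_fractions(self) -> dict[str, float]:
        return {s: float(np.mean(self.states == s)) for s in STATES}


@dataclass
class TemperatureTrace:
    """Per-epoch cortical temperature in degrees Celsius."""

    values: np.ndarray
    epoch_s: float = 4.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0:
            raise ValueError("temperature trace must contain at least one epoch")
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be positive")
        if np.isinf(values).any():
            raise ValueError("temperature trace contains infinite values")
        self.values = values

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_epochs(self) -> int:
        return int(self.values.size)

    @property
    def has_nan(self) -> bool:
        return bool(np.isnan(self.values).any())

    def require_complete(self) -> "TemperatureTrace":
        """Return self, raising if any value is NaN."""
        if self.has_nan:
            n = int(np.isnan(self.values).sum())
            raise ValueError(f"temperature trace contains {n} NaN value(s)")
        return self


def read_hypnogram(
    path: str | Path,
    dialect: str = "plain",
    epoch_s: float = 4.0,
    **kwargs,
) -> Hypnogram:
    """Read a hypnogram from a plain token file or a CSV with a ``state`` column.

    Recognized tokens: ``w/W/1 -> W``, ``n/N/2 -> N``, ``r/R/3 -> R``;
    artefact-suffixed variants (``"W*"``, ``"1a"``) map to their underlying
    state. Unknown tokens raise a :class:`ValueError` naming the line.
    """
    path = Path(path)
    if dialect == "plain":
        tokens = [
            (i, line.strip())
            for i, line in enumerate(path.read_text().splitlines(), start=1)
            if line.strip()
        ]
        if not tokens:
            raise ValueError(f"{path}: empty hypnogram file")
        states = []
        for lineno, tok in tokens:
            try:
                states.append(_map_token(tok))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
        return Hypnogram(np.array(states), epoch_s=epoch_s, **kwargs)
    if dialect == "csv":
        df = pd.read_csv(path)
        if "state" not in df.columns:
            raise ValueError(f"{path}: CSV hypnogram needs a 'state' column")
        if df.empty:
            raise ValueError(f"{path}: empty hypnogram file")
        states = []
        for idx, tok in enumerate(df["state"].astype(str)):
            try:
                states.append(_map_token(tok))
            except ValueError as err:
                raise ValueError(f"{path}: row {idx}: {err}") from None
        hyp = Hypnogram(np.array(states), epoch_s=epoch_s, **kwargs)
        if "zt_h" in df.columns:
            expected = hyp.zt_h() % 24.0
            got = df["zt_h"].to_numpy(dtype=float) % 24.0
            if not np.allclose(got, expected, atol=1e-6):
                raise ValueError(f"{path}: zt_h column inconsistent with epoch grid")
        return hyp
    raise ValueError(f"unknown hypnogram dialect {dialect!r}")


def write_hypnogram(hyp: Hypnogram, path: str | Path, dialect: str = "plain") -> None:
    path = Path(path)
    if dialect == "plain":
        path.write_text("\n".join(hyp.states) + "\n")
    elif dialect == "csv":
        pd.DataFrame({"state": hyp.states}).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown hypnogram dialect {dialect!r}")


def read_temperature(path: str | Path, epoch_s: float = 4.0) -> TemperatureTrace:
    """Read a temperature trace: CSV with a ``temp_c`` column or a headerless
    single column, one value per epoch. NaNs are allowed on read but flagged;
    operations that require complete data reject traces containing them.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    if not first:
        raise ValueError(f"{path}: empty temperature file")
    if first.split(",")[0] == "temp_c" or "temp_c" in first.split(","):
        col = pd.read_csv(path, float_precision="round_trip")["temp_c"]
        values = col.to_numpy(dtype=float)
        return TemperatureTrace(values, epoch_s=epoch_s)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip().split(",")[0]
            if not tok:
                continue
            if tok.lower() == "nan":
                values.append(math.nan)
                continue
            try:
                values.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric temperature {tok!r}"
                ) from None
    return TemperatureTrace(np.array(values), epoch_s=epoch_s)


def write_temperature(
    trace: TemperatureTrace, path: str | Path, decimals: int | None = None
) -> None:
    """Write a temperature CSV with a ``temp_c`` header column.

    With ``decimals=None`` values are written at full precision (shortest
    round-tripping representation); an integer fixes the decimal places.
    """
    path = Path(path)
    if decimals is None:
        body = "\n".join(repr(float(v)) for v in trace.values)
    else:
        body = "\n".join(f"{v:.{decimals}f}" for v in trace.values)
    path.write_text("temp_c\n" + body + "\n")


def read_recording_spreadsheet(
    path: str | Path,
    sheet: int | str = 0,
    state_col: int = 0,
    temp_col: int = 1,
    epoch_s: float = 4.0,
) -> tuple[Hypnogram, TemperatureTrace]:
    """Convenience reader for a two-column spreadsheet (state, temperature).

    The column layout is a guess at a common scoring-export format and is
    isolated here; prefer the CSV readers for anything scripted.
    """
    df = pd.read_excel(path, sheet_name=sheet, header=None)
    states = [str(s) for s in df.iloc[:, state_col]]
    temps = df.iloc[:, temp_col].to_numpy(dtype=float)
    hyp = Hypnogram(np.array([_map_token(s) for s in states]), epoch_s=epoch_s)
    return hyp, TemperatureTrace(temps, epoch_s=epoch_s)


def validate_pair(
    hyp: Hypnogram, temp: TemperatureTrace
) -> tuple[Hypnogram, TemperatureTrace]:
    """Check that a hypnogram and temperature trace are alignable.

    Returns the pair unchanged iff lengths and epoch durations match.
    """
    if hyp.n_epochs != temp.n_epochs:
        raise ValueError(
            f"length mismatch: hypnogram has {hyp.n_epochs} epochs, "
            f"temperature trace has {temp.n_epochs}"
        )
    if hyp.epoch_s != temp.epoch_s:
        raise ValueError(
            f"epoch duration mismatch: hypnogram {hyp.epoch_s} s, "
            f"temperature trace {temp.epoch_s} s"
        )
    return hyp, temp
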