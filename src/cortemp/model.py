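"""Forward simulation of cortical temperature from a sleep-wake sequence.

The model treats cortical temperature as relaxing exponentially toward a
state-dependent asymptote: during wakefulness and REM sleep, toward an upper
asymptote U with time constant tau_WR; during NREM sleep, toward a lower
asymptote L with time constant tau_N. One update per 4-s epoch:

    wake/REM:  T(t) = U(t) - (U(t) - T(t-1)) * exp(-dt / tau_WR)
    NREM:      T(t) = L(t) + (T(t-1) - L(t)) * exp(-dt / tau_N)

with dt the epoch duration in hours (exactly epoch_s/3600). The basic model
(Model 0) keeps both asymptotes constant. Two optional factors shift BOTH
asymptotes in parallel, preserving the inter-asymptote distance:

* prior wake prevalence (Model 1): the fraction of wake+REM time in a lagged
  multi-hour window, mean-centered and doubled to span [-1, +1], scaled to
  degrees Celsius; sustained wakefulness transiently raises the defended
  temperature range;
* a circadian sinusoid (Model 2): a 24-h sine of the Zeitgeber time with
  free amplitude and phase, whose trough falls at ZT (6 + phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .hypnogram import Hypnogram, TemperatureTrace

__all__ = [
    "ModelParams",
    "AsymptoteTraces",
    "wake_prevalence",
    "pw_modulation",
    "circadian_modulation",
    "build_asymptotes",
    "simulate",
    "median_params",
]


@dataclass
class ModelParams:
    """Full parameter vector of the temperature model.

    Attributes
    ----------
    L_base, U_base
        Lower/upper asymptote base values, deg C. ``U_base > L_base``.
    tau_wr, tau_n
        Wake/REM and NREM time constants, hours. Each is the time needed to
        close ~63% of the gap to the corresponding asymptote.
    pw_size
        Prior-wake-prevalence window size, hours (0 disables the factor).
    pw_shift
        Hours between the window end and the evaluated time point; negative
        values place the window further in the past. The unshifted window
        ends at the preceding epoch.
    pw_scale
        Deg C per unit mean-centered-doubled prevalence, i.e. the maximum
        possible asymptote modulation at 100% wakefulness.
    circ_amp
        Circadian sine amplitude, deg C (0 disables the factor).
    circ_phase
        Circadian phase, hours; the asymptote trough falls at ZT (6 + phase).
    T0
        Temperature immediately preceding the first epoch, deg C.
    enable_pw, enable_circ
        Factor flags: Model 0 = both off, Model 1 = prevalence only,
        Model 2 = both on.
    """

    L_base: float
    U_base: float
    tau_wr: float
    tau_n: float
    pw_size: float = 0.0
    pw_shift: float = 0.0
    pw_scale: float = 0.0
    circ_amp: float = 0.0
    circ_phase: float = 0.0
    T0: float = 35.0
    enable_pw: bool = False
    enable_circ: bool = False

    def __post_init__(self) -> None:
        if not self.U_base > self.L_base:
            raise ValueError(
                f"U_base ({self.U_base}) must exceed L_base ({self.L_base})"
            )
        if not (self.tau_wr > 0 and self.tau_n > 0):
            raise ValueError("time constants must be positive")
        if self.pw_size < 0:
            raise ValueError("pw_size must be >= 0")
        if self.pw_scale < 0:
            raise ValueError("pw_scale must be >= 0")
        if self.circ_amp < 0:
            raise ValueError("circ_amp must be >= 0")
        if not math.isfinite(self.T0):
            raise ValueError("T0 must be finite")

    @property
    def model_variant(self) -> int:
        """0, 1, or 2 according to which factors are enabled."""
        if self.enable_circ:
            return 2
        return 1 if self.enable_pw else 0

    def with_variant(self, variant: int) -> "ModelParams":
        if variant not in (0, 1, 2):
            raise ValueError("model variant must be 0, 1, or 2")
        return replace(self, enable_pw=variant >= 1, enable_circ=variant == 2)

    def to_dict(self) -> dict:
        return {
            "L_base": float(self.L_base), "U_base": float(self.U_base),
            "tau_wr": float(self.tau_wr), "tau_n": float(self.tau_n),
            "pw_size": float(self.pw_size), "pw_shift": float(self.pw_shift),
            "pw_scale": float(self.pw_scale),
            "circ_amp": float(self.circ_amp),
            "circ_phase": float(self.circ_phase),
            "T0": float(self.T0),
            "enable_pw": bool(self.enable_pw),
            "enable_circ": bool(self.enable_circ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def median_params() -> ModelParams:
    """The bundled across-animal median Model 2 parameter set.

    These are the published median optimized values (asymptotes 34.26/36.28
    deg C, time constants 0.21/0.11 h, prevalence window 3.0 h with -1.4 h
    shift and 1.01 deg C scale, circadian amplitude 0.19 deg C with phase
    -0.63 h) used for predicting temperature in recordings that have no
    temperature data.
    """
    with resources.files("cortemp.data").joinpath("median_params.yaml").open() as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


@dataclass
class AsymptoteTraces:
    """Per-epoch lower and upper asymptotes, deg C."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("asymptote traces must have equal length")
        if not np.all(self.upper > self.lower):
            raise ValueError("upper asymptote must exceed lower at every epoch")


def _epochs(hours: float, epoch_s: float) -> int:
    return int(round(hours * 3600.0 / epoch_s))


def wake_prevalence(
    hyp: Hypnogram, pw_size: float, pw_shift: float
) -> np.ndarray:
    """Fraction of wake+REM time in a lagged window, per epoch.

    For epoch t the window spans ``[t + pw_shift - pw_size, t + pw_shift)``
    hours; with ``pw_shift = 0`` it ends at the preceding epoch. Window
    positions before the recording start are backfilled with the mean of the
    two baseline days at the same clock offset (requiring >= 48 h of
    recording; shorter recordings fall back to the whole-recording mean
    prevalence). Windows extending beyond the recording end yield NaN, a
    sentinel that downstream modulation maps to zero.
    """
    if pw_size <= 0:
        raise ValueError("pw_size must be positive")
    n = hyp.n_epochs
    n_win = _epochs(pw_size, hyp.epoch_s)
    n_shift = _epochs(pw_shift, hyp.epoch_s)
    if n_win < 1:
        raise ValueError("pw_size shorter than one epoch")
    active = hyp.is_active.astype(float)

    n_day = _epochs(24.0, hyp.epoch_s)
    lookback = max(0, n_win - n_shift)  # lowest index accessed is -lookback
    if lookback > 0:
        if n >= 2 * n_day:
            if lookback > n_day:
                raise ValueError(
                    "prevalence window reaches more than 24 h before start"
                )
            # indicator before t=0: average of the two baseline days at the
            # same clock offset
            pre = 0.5 * (
                active[n_day - lookback : n_day]
                + active[2 * n_day - lookback : 2 * n_day]
            )
        else:
            pre = np.full(lookback, active.mean())
        ext = np.concatenate([pre, active])
    else:
        ext = active

    csum = np.concatenate([[0.0], np.cumsum(ext)])
    t = np.arange(n)
    hi = t + n_shift + lookback          # exclusive end index into ext
    lo = hi - n_win
    prev = np.full(n, np.nan)
    ok = hi <= ext.size
    prev[ok] = (csum[hi[ok]] - csum[lo[ok]]) / n_win
    return prev


def pw_modulation(
    hyp: Hypnogram, pw_size: float, pw_shift: float, pw_scale: float
) -> np.ndarray:
    """Asymptote offset (deg C) from prior wake prevalence, per epoch.

    The windowed prevalence is centered on the whole-recording wake+REM
    fraction and doubled, so it spans [-1, +1]; the scale is therefore the
    maximum possible modulation of either asymptote. NaN window positions
    (beyond the recording end) contribute zero modulation.
    """
    prev = wake_prevalence(hyp, pw_size, pw_shift)
    mean_frac = hyp.is_active.mean()
    offset = (prev - mean_frac) * 2.0 * pw_scale
    return np.where(np.isnan(offset), 0.0, offset)


def circadian_modulation(
    n_epochs: int,
    epoch_s: float,
    circ_amp: float,
    circ_phase: float,
    start_zt_h: float = 0.0,
) -> np.ndarray:
    """Circadian asymptote offset (deg C) per epoch.

    ``offset(t) = -circ_amp * sin(2*pi * (zt(t) - circ_phase) / 24)`` with
    zt in hours after light onset. The sign convention anchors the trough of
    the offset at ZT (6 + circ_phase): the defended temperature range is
    lowest near the light-period midpoint for phases near zero.
    """
    if circ_amp < 0:
        raise ValueError("circ_amp must be >= 0")
    zt = start_zt_h + np.arange(n_epochs) * (epoch_s / 3600.0)
    return -circ_amp * np.sin(2.0 * np.pi * (zt - circ_phase) / 24.0)


def build_asymptotes(hyp: Hypnogram, params: ModelParams) -> AsymptoteTraces:
    """Materialize the per-epoch asymptote vectors for a hypnogram.

    Both factors shift the lower and upper asymptotes in parallel, so the
    inter-asymptote distance stays ``U_base - L_base`` at every epoch.
    """
    offset = np.zeros(hyp.n_epochs)
    if params.enable_pw and params.pw_size > 0:
        offset = offset + pw_modulation(
            hyp, params.pw_size, params.pw_shift, params.pw_scale
        )
    if params.enable_circ:
        offset = offset + circadian_modulation(
            hyp.n_epochs, hyp.epoch_s, params.circ_amp, params.circ_phase,
            hyp.start_zt_h,
        )
    return AsymptoteTraces(params.L_base + offset, params.U_base + offset)


@njit(cache=True)
def _relax(is_active, lower, upper, k_wr, k_n, t0):  # pragma: no cover - jit
    n = is_active.size
    out = np.empty(n)
    prev = t0
    for i in range(n):
        if is_active[i]:
            prev = upper[i] + (prev - upper[i]) * k_wr
        else:
            prev = lower[i] + (prev - lower[i]) * k_n
        out[i] = prev
    return out


def simulate(hyp: Hypnogram, params: ModelParams) -> TemperatureTrace:
    """Forward-simulate cortical temperature for a hypnogram.

    Each epoch applies one exponential update toward the asymptote of its
    state; ``params.T0`` is the temperature immediately preceding the first
    epoch. Output has one value per hypnogram epoch.
    """
    asy = build_asymptotes(hyp, params)
    dt = hyp.dt_h
    k_wr = math.exp(-dt / params.tau_wr)
    k_n = math.exp(-dt / params.tau_n)
    values = _relax(hyp.is_active, asy.lower, asy.upper, k_wr, k_n, params.T0)
    if np.isnan(values).any():
        raise FloatingPointError("simulation produced NaN values")
    return TemperatureTrace(values, epoch_s=hyp.epoch_s)
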