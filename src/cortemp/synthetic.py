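"""Synthetic hypnograms and temperature recordings.

Real recordings follow a fixed 96-h design: two baseline days under a
12:12 light-dark cycle, 6 h of sleep deprivation (enforced wakefulness)
from light onset of day 3, then recovery. The generator emulates the
features the temperature model is sensitive to — 4-s epochs, light/dark
modulated bout structure, sparse REM sleep (~6% of recording time), an
optional sleep-deprivation block — and produces temperature as the forward
simulation of a known parameter set plus i.i.d. Gaussian measurement noise.
Bout lengths are geometric (memoryless) at epoch resolution; the
temperature model is agnostic to the bout-length distribution, so realism
beyond state fractions and bout scale is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypnogram import Hypnogram, TemperatureTrace
from .model import ModelParams, median_params, simulate

__all__ = ["SynthConfig", "generate_hypnogram", "generate_recording"]


def _default_bouts() -> dict[str, float]:
    return {"W": 8.0, "N": 4.0, "R": 1.2}


@dataclass
class SynthConfig:
    """Synthetic-recording configuration.

    ``mean_bout_min`` gives per-state mean bout durations (minutes) during
    the light phase; wake bouts are multiplied by ``light_dark_wake_bias``
    in the dark phase, reproducing the nocturnal activity pattern. NREM
    bouts end into REM sleep with probability ``rem_entry_prob`` (else
    wake); REM bouts always end into wake. ``sd_block`` overwrites a
    ``(start_h, dur_h)`` interval with continuous wakefulness, emulating
    sleep deprivation by gentle handling. Temperature is the forward
    simulation of ``true_params`` (the bundled published medians by
    default) plus Gaussian noise of SD ``noise_sd``.
    """

    duration_h: float = 96.0
    epoch_s: float = 4.0
    mean_bout_min: dict[str, float] = field(default_factory=_default_bouts)
    rem_entry_prob: float = 0.75
    light_dark_wake_bias: float = 2.0
    sd_block: tuple[float, float] | None = (48.0, 6.0)
    true_params: ModelParams | None = None
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mean_bout_min.values()):
            raise ValueError("mean bout durations must be positive")
        if not 0 <= self.rem_entry_prob <= 1:
            raise ValueError("rem_entry_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def params(self) -> ModelParams:
        return self.true_params if self.true_params is not None else median_params()


def generate_hypnogram(cfg: SynthConfig) -> Hypnogram:
    """Draw a semi-Markov state sequence with light/dark bout modulation.

    Bout lengths are geometric with the configured means (in epochs, at
    least one epoch); the light/dark wake bias is decided by the Zeitgeber
    time at bout onset. Fully deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * 3600.0 / cfg.epoch_s))
    dt_h = cfg.epoch_s / 3600.0
    states = np.empty(n, dtype="<U1")
    i = 0
    state = "W"
    while i < n:
        mean_min = cfg.mean_bout_min[state]
        if state == "W" and (i * dt_h) % 24.0 >= 12.0:
            mean_min *= cfg.light_dark_wake_bias
        mean_epochs = max(1.0, mean_min * 60.0 / cfg.epoch_s)
        length = int(rng.geometric(1.0 / mean_epochs))
        states[i : i + length] = state
        i += length
        if state == "W":
            state = "N"
        elif state == "N":
            state = "R" if rng.random() < cfg.rem_entry_prob else "W"
        else:
            state = "W"
    sd_intervals = []
    if cfg.sd_block is not None:
        start_h, dur_h = cfg.sd_block
        lo = int(round(start_h / dt_h))
        hi = min(n, int(round((start_h + dur_h) / dt_h)))
        if lo < n:
            states[lo:hi] = "W"
            sd_intervals.append((start_h, min(start_h + dur_h, n * dt_h)))
    return Hypnogram(states, epoch_s=cfg.epoch_s, sd_intervals=sd_intervals)


def generate_recording(cfg: SynthConfig) -> tuple[Hypnogram, TemperatureTrace]:
    """Generate a hypnogram plus matching noisy temperature trace.

    Temperature is ``simulate(hypnogram, cfg.true_params)`` with i.i.d.
    Gaussian(0, noise_sd^2) measurement noise added; deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # independent of state draws
    hyp = generate_hypnogram(cfg)
    clean = simulate(hyp, cfg.params())
    noisy = clean.values + rng.normal(0.0, cfg.noise_sd, size=hyp.n_epochs) \
        if cfg.noise_sd > 0 else clean.values.copy()
    return hyp, TemperatureTrace(noisy, epoch_s=cfg.epoch_s)
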