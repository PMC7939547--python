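"""Goodness-of-fit metrics, hourly residual statistics, and the
three-factor variance decomposition.

Fits are summarized by the epoch-level RMS error and the Pearson
correlation between simulated and recorded temperature; correlations are
averaged after Fisher (atanh) transformation. Systematic misfit over the
day is assessed by hourly mean residuals across animals, tested per hour by
paired t-tests with Benjamini-Hochberg false-discovery-rate correction.
The variance explained by the full model is partitioned into unique and
pairwise-shared contributions of its three factors: the sleep-wake
sequence, prior wake prevalence, and the circadian sinusoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hypnogram import Hypnogram, TemperatureTrace, validate_pair
from .model import ModelParams, simulate

__all__ = [
    "ResidualReport",
    "VarianceDecomposition",
    "rms_error",
    "fisher_mean_r",
    "hourly_residual_report",
    "decompose_variance",
    "mean_level_adjust",
]


def rms_error(sim: TemperatureTrace, temp: TemperatureTrace) -> float:
    """Root-mean-square difference between two aligned traces, deg C."""
    if sim.n_epochs != temp.n_epochs:
        raise ValueError("traces must have equal length")
    sim.require_complete()
    temp.require_complete()
    return float(np.sqrt(np.mean((sim.values - temp.values) ** 2)))


def fisher_mean_r(rs: Sequence[float]) -> float:
    """Average correlation coefficients after Fisher transformation:
    tanh(mean(atanh(r)))."""
    rs = np.asarray(rs, dtype=float)
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    return float(np.tanh(np.mean(np.arctanh(rs))))


@dataclass
class ResidualReport:
    """Hourly residual (simulated minus recorded) statistics across animals.

    ``mean_resid`` has one row per animal and one column per hour;
    statistical fields are None for single-animal input. ``residual_rms``
    is the RMS of the across-animal mean hourly residual vector — the
    effect size of systematic hourly misfit.
    """

    hour_mid: np.ndarray
    mean_resid: np.ndarray          # (n_animals, n_hours)
    grand_mean: np.ndarray          # (n_hours,)
    grand_sd: np.ndarray
    residual_rms: float
    t_stat: np.ndarray | None = None
    p_value: np.ndarray | None = None
    q_value: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float = 0.05


def hourly_residual_report(
    pairs: Sequence[tuple[TemperatureTrace, TemperatureTrace]],
    epoch_s: float = 4.0,
    alpha: float = 0.05,
) -> ResidualReport:
    """Per-hour residual report across animals.

    ``pairs`` holds one ``(recorded, simulated)`` pair per animal, all of
    equal length. For each hour the per-animal mean residual (simulated
    minus recorded) is computed; across animals each hour is tested against
    zero by a two-sided paired t-test of the hourly simulated vs recorded
    means, and p-values are Benjamini-Hochberg corrected across hours.
    Hourly values are indexed at the interval midpoint.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (recorded, simulated) pair")
    n = pairs[0][0].n_epochs
    per_hour = int(round(3600.0 / epoch_s))
    n_hours = n // per_hour
    if n_hours < 1:
        raise ValueError("recording shorter than one hour")
    rows = []
    for temp, sim in pairs:
        if temp.n_epochs != n or sim.n_epochs != n:
            raise ValueError("all pairs must have equal length")
        resid = sim.values - temp.values
        rows.append(
            resid[: n_hours * per_hour].reshape(n_hours, per_hour).mean(axis=1)
        )
    mean_resid = np.vstack(rows)
    grand_mean = mean_resid.mean(axis=0)
    grand_sd = mean_resid.std(axis=0, ddof=1) if len(pairs) > 1 \
        else np.zeros(n_hours)
    report = ResidualReport(
        hour_mid=np.arange(n_hours) + 0.5,
        mean_resid=mean_resid,
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        residual_rms=float(np.sqrt(np.mean(grand_mean**2))),
        alpha=alpha,
    )
    if len(pairs) < 2:
        return report
    # paired t-test of hourly sim vs data means == one-sample test of resid
    t_stat, p_value = stats.ttest_1samp(mean_resid, 0.0, axis=0)
    reject, q_value, _, _ = multipletests(p_value, alpha=alpha, method="fdr_bh")
    return replace(
        report, t_stat=t_stat, p_value=p_value, q_value=q_value,
        significant=reject,
    )


def mean_level_adjust(
    temp: TemperatureTrace, pred: TemperatureTrace
) -> TemperatureTrace:
    """Shift recorded data to the mean level of a prediction (scale kept).

    Useful when absolute temperature levels are off for technical reasons
    but the dynamics are intact.
    """
    if temp.n_epochs != pred.n_epochs:
        raise ValueError("traces must have equal length")
    shift = float(np.mean(pred.values) - np.mean(temp.values))
    return TemperatureTrace(temp.values + shift, epoch_s=temp.epoch_s)


@dataclass
class VarianceDecomposition:
    """Unique and pairwise-shared explained-variance fractions.

    Fractions are of the recorded-temperature variance. ``total_*`` is the
    unique fraction of a factor plus its two pairwise shares;
    ``interaction_remainder`` is the three-way term left over when the six
    unique/shared components are subtracted from the full model's variance
    fraction (reported, not distributed).
    """

    unique_sw: float
    unique_pw: float
    unique_circ: float
    shared_sw_pw: float
    shared_sw_circ: float
    shared_pw_circ: float
    total_sw: float
    total_pw: float
    total_circ: float
    total_model: float
    r_squared: float
    interaction_remainder: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def decompose_variance(
    hyp: Hypnogram,
    temp: TemperatureTrace,
    params: ModelParams,
    sw_trace_mode: str = "model0_sim",
) -> VarianceDecomposition:
    """Partition the model's explained variance among its three factors.

    The full-model output is disassembled into three factor traces: the
    circadian trace is the full simulation minus the simulation with the
    circadian amplitude zeroed; the prevalence trace likewise with the
    prevalence scale zeroed; and the sleep-wake trace is, by default, the
    simulation with both factors off (``sw_trace_mode="model0_sim"``).
    The alternative reading ``sw_trace_mode="residual"`` defines it as the
    full output minus the two difference traces. Unique fractions are
    var(trace)/var(data); the share of a factor pair is
    var(trace_i + trace_j)/var(data) minus both unique fractions
    (algebraically 2*cov/var).
    """
    validate_pair(hyp, temp)
    temp.require_complete()
    var_data = float(np.var(temp.values))
    if var_data == 0:
        raise ValueError("recorded temperature has zero variance")
    full = replace(params, enable_pw=True, enable_circ=True)
    s_full = simulate(hyp, full).values
    s_no_circ = simulate(hyp, replace(full, circ_amp=0.0)).values
    s_no_pw = simulate(hyp, replace(full, pw_scale=0.0)).values
    circ_trace = s_full - s_no_circ
    pw_trace = s_full - s_no_pw
    if sw_trace_mode == "model0_sim":
        sw_trace = simulate(
            hyp, replace(full, circ_amp=0.0, pw_scale=0.0)
        ).values
    elif sw_trace_mode == "residual":
        sw_trace = s_full - circ_trace - pw_trace
    else:
        raise ValueError("sw_trace_mode must be 'model0_sim' or 'residual'")

    def frac(x: np.ndarray) -> float:
        return float(np.var(x)) / var_data

    u_sw, u_pw, u_circ = frac(sw_trace), frac(pw_trace), frac(circ_trace)
    sh_sw_pw = frac(sw_trace + pw_trace) - u_sw - u_pw
    sh_sw_circ = frac(sw_trace + circ_trace) - u_sw - u_circ
    sh_pw_circ = frac(pw_trace + circ_trace) - u_pw - u_circ
    total_model = frac(s_full)
    r = np.corrcoef(s_full, temp.values)[0, 1]
    components = u_sw + u_pw + u_circ + sh_sw_pw + sh_sw_circ + sh_pw_circ
    return VarianceDecomposition(
        unique_sw=u_sw,
        unique_pw=u_pw,
        unique_circ=u_circ,
        shared_sw_pw=sh_sw_pw,
        shared_sw_circ=sh_sw_circ,
        shared_pw_circ=sh_pw_circ,
        total_sw=u_sw + sh_sw_pw + sh_sw_circ,
        total_pw=u_pw + sh_sw_pw + sh_pw_circ,
        total_circ=u_circ + sh_sw_circ + sh_pw_circ,
        total_model=total_model,
        r_squared=float(r**2),
        interaction_remainder=total_model - components,
    )
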