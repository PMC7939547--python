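"""Forward model: prevalence windows, circadian modulation, simulation.

The optimized (numba) simulation kernel and the vectorized prevalence
machinery are each cross-checked against naive per-epoch Python loops that
implement the documented contracts independently.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from cortemp import (
    Hypnogram,
    ModelParams,
    build_asymptotes,
    circadian_modulation,
    pw_modulation,
    simulate,
    wake_prevalence,
)
from conftest import random_hypnogram

EPOCHS_PER_DAY = 21600  # 24 h at 4-s epochs


# ---------------------------------------------------------------------------
# independent loop oracles

def prevalence_oracle(hyp, size_h, shift_h, t):
    """Windowed wake+REM fraction at epoch t, by explicit per-epoch loop.

    Pre-start epochs contribute the mean of the two baseline days at the
    same clock offset (whole-recording mean if the recording is < 48 h);
    windows past the recording end yield NaN.
    """
    eps = hyp.epoch_s
    n_win = round(size_h * 3600 / eps)
    n_shift = round(shift_h * 3600 / eps)
    n_day = round(24 * 3600 / eps)
    active = hyp.is_active.astype(float)
    short = hyp.n_epochs < 2 * n_day

    def indicator(i):
        if i >= 0:
            return active[i]
        if short:
            return active.mean()
        return 0.5 * (active[i + n_day] + active[i + 2 * n_day])

    hi = t + n_shift
    if hi > hyp.n_epochs:
        return math.nan
    return sum(indicator(i) for i in range(hi - n_win, hi)) / n_win


def simulate_oracle(hyp, params):
    """Naive per-epoch simulation, independent of the numba kernel and the
    vectorized asymptote construction."""
    n = hyp.n_epochs
    dt = hyp.epoch_s / 3600.0
    mean_frac = hyp.is_active.mean()
    out = np.empty(n)
    prev = params.T0
    for t in range(n):
        offset = 0.0
        if params.enable_pw and params.pw_size > 0:
            p = prevalence_oracle(hyp, params.pw_size, params.pw_shift, t)
            if not math.isnan(p):
                offset += (p - mean_frac) * 2.0 * params.pw_scale
        if params.enable_circ:
            zt = hyp.start_zt_h + t * dt
            offset += -params.circ_amp * math.sin(
                2 * math.pi * (zt - params.circ_phase) / 24.0
            )
        if hyp.states[t] in ("W", "R"):
            u = params.U_base + offset
            prev = u - (u - prev) * math.exp(-dt / params.tau_wr)
        else:
            lo = params.L_base + offset
            prev = lo + (prev - lo) * math.exp(-dt / params.tau_n)
        out[t] = prev
    return out


# ---------------------------------------------------------------------------
# prior wake prevalence

class TestWakePrevalence:
    def test_all_wake_is_one(self):
        hyp = Hypnogram(np.array(["W"] * 2 * EPOCHS_PER_DAY))
        prev = wake_prevalence(hyp, 1.0, 0.0)
        ok = ~np.isnan(prev)
        np.testing.assert_allclose(prev[ok], 1.0)

    def test_alternating_is_half(self):
        states = np.tile(["W", "N"], EPOCHS_PER_DAY)
        hyp = Hypnogram(states)
        prev = wake_prevalence(hyp, 2.0, 0.0)
        ok = ~np.isnan(prev)
        assert np.nanmax(np.abs(prev[ok] - 0.5)) <= 1.0 / (2 * 3600 / 4)

    @pytest.mark.parametrize("size,shift", [(3.0, -1.4), (1.0, 0.5), (0.5, 0.0)])
    def test_matches_loop_oracle(self, recording_96h, size, shift):
        hyp, _ = recording_96h
        prev = wake_prevalence(hyp, size, shift)
        for t in [0, 1, 500, 4321, 43210, 86000, 86399]:
            expected = prevalence_oracle(hyp, size, shift, t)
            if math.isnan(expected):
                assert math.isnan(prev[t])
            else:
                assert prev[t] == pytest.approx(expected, abs=1e-12)

    def test_short_recording_uses_mean_backfill(self, rng):
        hyp = random_hypnogram(rng, 3600)  # 4 h, no two baseline days
        prev = wake_prevalence(hyp, 1.0, -0.5)
        t = 10  # window lies almost entirely before the recording start
        assert prev[t] == pytest.approx(prevalence_oracle(hyp, 1.0, -0.5, t))

    def test_rejects_nonpositive_size(self, recording_96h):
        with pytest.raises(ValueError):
            wake_prevalence(recording_96h[0], 0.0, 0.0)


class TestPwModulation:
    def test_prevalence_at_global_mean_gives_zero(self):
        states = np.tile(["W", "N"], EPOCHS_PER_DAY)
        hyp = Hypnogram(states)
        offset = pw_modulation(hyp, 2.0, 0.0, 1.0)
        assert np.nanmax(np.abs(offset)) <= 2.0 / (2 * 3600 / 4)

    def test_scale_is_max_modulation_at_full_wake(self, recording_96h):
        """At 100% wake in the window vs a 50% global mean, the offset is
        the scale itself: (1.0 - 0.5) * 2 * scale."""
        states = np.tile(["W", "N"], EPOCHS_PER_DAY)
        states[:3600] = "W"  # first 4 h continuous wake
        hyp = Hypnogram(states)
        mean_frac = hyp.is_active.mean()
        offset = pw_modulation(hyp, 2.0, 0.0, 1.01)
        t = 3600  # window covers the all-wake stretch
        assert offset[t] == pytest.approx((1.0 - mean_frac) * 2 * 1.01)

    def test_derived_example(self):
        """Global mean 0.5, window prevalence 0.75, scale 1.0 -> +0.5 degC."""
        assert (0.75 - 0.5) * 2 * 1.0 == pytest.approx(0.5)

    def test_sentinel_beyond_end_is_zero(self, recording_96h):
        hyp, _ = recording_96h
        offset = pw_modulation(hyp, 1.0, 0.5, 1.0)
        assert np.all(offset[-100:] == 0.0)


# ---------------------------------------------------------------------------
# circadian modulation

class TestCircadianModulation:
    def test_zero_amplitude_zero_offset(self):
        offset = circadian_modulation(1000, 4.0, 0.0, -0.63)
        assert np.all(offset == 0.0)

    def test_trough_at_zt_6_plus_phase(self):
        """Amplitude 0.19, phase -0.63 -> minimum -0.19 degC at ZT 5.37."""
        offset = circadian_modulation(EPOCHS_PER_DAY, 4.0, 0.19, -0.63)
        t_min = int(np.argmin(offset))
        assert t_min * 4 / 3600 == pytest.approx(5.37, abs=1e-9)
        assert offset[t_min] == pytest.approx(-0.19)

    def test_peak_half_cycle_after_trough(self):
        offset = circadian_modulation(EPOCHS_PER_DAY, 4.0, 0.19, -0.63)
        t_max = int(np.argmax(offset))
        assert t_max * 4 / 3600 == pytest.approx(17.37, abs=1e-9)
        assert offset[t_max] == pytest.approx(0.19)

    def test_start_zt_shifts_phase(self):
        a = circadian_modulation(100, 4.0, 0.2, 0.0, start_zt_h=6.0)
        b = circadian_modulation(100 + 5400, 4.0, 0.2, 0.0, start_zt_h=0.0)
        np.testing.assert_allclose(a, b[5400:], atol=1e-12)


# ---------------------------------------------------------------------------
# asymptote construction and simulation

class TestBuildAsymptotes:
    def test_flags_off_constant(self, rng):
        hyp = random_hypnogram(rng, 1000)
        p = ModelParams(34.0, 36.0, 0.2, 0.1)
        asy = build_asymptotes(hyp, p)
        assert np.all(asy.lower == 34.0) and np.all(asy.upper == 36.0)

    def test_all_wake_pw_raises_both_equally(self):
        hyp = Hypnogram(np.array(["W"] * 2 * EPOCHS_PER_DAY))
        p = ModelParams(34.0, 36.0, 0.2, 0.1, pw_size=1.0, pw_shift=0.0,
                        pw_scale=1.0, enable_pw=True)
        asy = build_asymptotes(hyp, p)
        np.testing.assert_allclose(asy.upper - asy.lower, 2.0)
        # constant prevalence == its own mean -> zero offset
        np.testing.assert_allclose(asy.lower, 34.0, atol=1e-12)

    def test_parallel_modulation_preserves_gap(self, recording_96h, medians):
        hyp, _ = recording_96h
        asy = build_asymptotes(hyp, medians)
        gap = asy.upper - asy.lower
        np.testing.assert_allclose(gap, medians.U_base - medians.L_base,
                                   atol=1e-12)

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError, match="U_base"):
            ModelParams(36.0, 34.0, 0.2, 0.1)


class TestSimulate:
    def test_fixed_point_at_upper(self):
        hyp = Hypnogram(np.array(["W"] * 500))
        p = ModelParams(34.0, 36.0, 0.2, 0.1, T0=36.0)
        np.testing.assert_allclose(simulate(hyp, p).values, 36.0)

    def test_one_time_constant_closes_63_percent(self):
        """0.2 h of continuous wake with tau_WR = 0.2 h closes 1 - 1/e of
        the gap: 36 - 2/e = 35.26424 degC."""
        n = int(0.2 * 900)  # 0.2 h of 4-s epochs
        hyp = Hypnogram(np.array(["W"] * n))
        p = ModelParams(34.0, 36.0, 0.2, 0.1, T0=34.0)
        final = simulate(hyp, p).values[-1]
        assert final == pytest.approx(36.0 - 2.0 * math.exp(-1.0), abs=1e-9)
        closed = (final - 34.0) / 2.0
        assert closed == pytest.approx(1 - math.exp(-1), abs=1e-6)

    def test_single_epoch_update(self):
        hyp = Hypnogram(np.array(["W"]))
        p = ModelParams(34.0, 36.0, 0.2, 0.1, T0=34.0)
        expected = 36.0 - 2.0 * math.exp(-(1.0 / 900.0) / 0.2)
        assert simulate(hyp, p).values[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(34.01108, abs=1e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hyp = random_hypnogram(rng, 1000)
        p = ModelParams(
            L_base=34.0 + rng.uniform(-0.5, 0.5),
            U_base=36.0 + rng.uniform(-0.5, 0.5),
            tau_wr=rng.uniform(0.05, 0.5),
            tau_n=rng.uniform(0.05, 0.5),
            pw_size=0.5, pw_shift=-0.2, pw_scale=rng.uniform(0, 1.5),
            circ_amp=rng.uniform(0, 0.3), circ_phase=rng.uniform(-2, 2),
            T0=35.0, enable_pw=True, enable_circ=True,
        )
        sim = simulate(hyp, p).values
        np.testing.assert_allclose(sim, simulate_oracle(hyp, p), atol=1e-10)

    def test_boundedness(self, rng):
        """Relaxation never overshoots the asymptote envelope."""
        hyp = random_hypnogram(rng, 2000)
        p = ModelParams(34.0, 36.0, 0.1, 0.05, circ_amp=0.3, circ_phase=1.0,
                        T0=35.0, enable_circ=True)
        asy = build_asymptotes(hyp, p)
        sim = simulate(hyp, p).values
        assert np.all(sim >= asy.lower.min() - 1e-12)
        assert np.all(sim <= asy.upper.max() + 1e-12)

    def test_semigroup_two_steps_equal_one_double_step(self):
        """Constant asymptotes: two same-state epochs == one 2*dt update."""
        hyp2 = Hypnogram(np.array(["W", "W"]), epoch_s=4.0)
        hyp1 = Hypnogram(np.array(["W"]), epoch_s=8.0)
        p = ModelParams(34.0, 36.0, 0.21, 0.11, T0=34.5)
        t2 = simulate(hyp2, p).values[-1]
        t1 = simulate(hyp1, p).values[-1]
        assert t2 == pytest.approx(t1, abs=1e-12)

    def test_model2_with_zero_factors_bit_identical_to_model0(self, rng):
        hyp = random_hypnogram(rng, 2 * EPOCHS_PER_DAY)
        p0 = ModelParams(34.26, 36.28, 0.21, 0.11, T0=35.3)
        p2 = replace(p0, pw_size=3.0, pw_shift=-1.4, pw_scale=0.0,
                     circ_amp=0.0, circ_phase=-0.63,
                     enable_pw=True, enable_circ=True)
        assert np.array_equal(simulate(hyp, p0).values, simulate(hyp, p2).values)

    def test_monotone_approach_under_constant_state(self):
        hyp = Hypnogram(np.array(["N"] * 500))
        p = ModelParams(34.0, 36.0, 0.2, 0.1, T0=35.5)
        sim = simulate(hyp, p).values
        gaps = np.abs(sim - 34.0)
        assert np.all(np.diff(gaps) < 0)

    def test_output_length_matches_hypnogram(self, rng):
        hyp = random_hypnogram(rng, 123)
        p = ModelParams(34.0, 36.0, 0.2, 0.1)
        assert simulate(hyp, p).n_epochs == 123
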