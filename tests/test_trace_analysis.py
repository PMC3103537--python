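"""Measurement pipeline: detection, randomness index, fits, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrap.burst_analysis import segment_bursts
from utrap.simulator import (
    FiringSequence,
    TrapParameters,
    WidthTrace,
    make_cohort,
    simulate_trap,
    synth_width_trace,
)
from utrap.trace_analysis import (
    classify_trap,
    detect_firings,
    fit_deflation_time,
    infer_pressure_ratio,
    randomness_index,
)


def flat_trace(n=100, level=500.0, noise=0.0, seed=0, dt=0.05):
    t = np.arange(n) * dt
    w = np.full(n, level)
    if noise:
        w = w + np.random.default_rng(seed).normal(0, noise, n)
    return WidthTrace(times=t, widths=w, dt=dt, noise_sd=noise)


class TestDetectFirings:
    def test_constant_trace_has_no_events(self):
        assert len(detect_firings(flat_trace())) == 0

    def test_too_short_trace_is_empty_not_error(self):
        tr = WidthTrace(times=np.array([0.0, 0.05]), widths=np.array([1.0, 2.0]), dt=0.05)
        assert len(detect_firings(tr)) == 0

    def test_recovers_noiseless_events_exactly(self):
        seq = FiringSequence(np.array([1.0, 2.5, 4.0, 5.5, 7.0]))
        tr = synth_width_trace(seq, tau=1.0, dt=0.02, noise_sd=0.0)
        det = detect_firings(tr)
        assert len(det) == 5
        assert np.abs(det.event_times - seq.event_times).max() <= tr.dt + 1e-12

    def test_no_false_positives_at_one_percent_noise(self):
        """Deep-deflation trace, 1e4 samples, jump_frac = 0.5: detection
        must flag the true firings and nothing else."""
        seq = FiringSequence(np.arange(1, 26) * 4.0)  # intervals of 4 tau
        tr = synth_width_trace(seq, tau=1.0, dt=0.01, noise_sd=1.2, seed=3)
        assert len(tr) >= 10_000
        det = detect_firings(tr, jump_frac=0.5)
        assert len(det) == len(seq)

    def test_waiting_trap_trace_yields_no_events(self):
        """A plateau-dominated trace (one initial deflation, then hours of
        noisy plateau) must not turn measurement noise into firings."""
        seq = FiringSequence(np.array([]))
        tr = synth_width_trace(seq, tau=1.5, dt=0.05, noise_sd=1.2,
                               seed=9, t_end=72.0)
        assert len(detect_firings(tr)) == 0


class TestRandomnessIndex:
    def test_constant_intervals_give_zero(self):
        assert randomness_index([1.5] * 10) == 0.0

    def test_hand_enumeration(self):
        assert randomness_index([1.0, 2.0, 1.0, 2.0]) == pytest.approx(1 / 1.5)

    def test_iid_exponential_tends_to_one(self):
        # E|X - Y| = 1/lambda for i.i.d. exponentials, so r -> 1
        iv = np.random.default_rng(0).exponential(2.5, 10_000)
        assert randomness_index(iv) == pytest.approx(1.0, abs=0.05)

    def test_needs_two_intervals(self):
        with pytest.raises(ValueError):
            randomness_index([1.0])

    def test_drift_robustness(self):
        # slow doubling of the period barely moves r
        iv = np.linspace(1.0, 2.0, 40)
        assert randomness_index(iv) < 0.05

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        iv=st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=30),
    )
    def test_scale_invariance(self, c, iv):
        iv = np.array(iv)
        assert randomness_index(c * iv) == pytest.approx(randomness_index(iv), rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(iv=st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=30))
    def test_zero_iff_constant(self, iv):
        iv = np.array(iv)
        assert (randomness_index(iv) == 0.0) == bool(np.all(iv == iv[0]))


class TestFitDeflationTime:
    def test_noiseless_exact_recovery(self):
        seq = FiringSequence(np.array([1.0, 3.0, 5.0, 7.0]))
        tr = synth_width_trace(seq, tau=1.2, dt=0.02, noise_sd=0.0)
        fit = fit_deflation_time(tr, seq)
        assert fit.tau_hat == pytest.approx(1.2, rel=1e-6)
        assert fit.w_inf_hat == pytest.approx(600.0, rel=1e-6)
        assert fit.w_def_hat == pytest.approx(480.0, rel=1e-6)

    def test_recovery_within_5pct_at_1pct_noise(self):
        seq = FiringSequence(np.array([1.0, 3.5, 6.0, 8.5, 11.0, 13.5]))
        tr = synth_width_trace(seq, tau=1.2, dt=0.02, noise_sd=1.2, seed=17)
        fit = fit_deflation_time(tr, seq)
        assert fit.n_segments >= 5
        assert fit.tau_hat == pytest.approx(1.2, rel=0.05)
        assert fit.tau_se > 0

    def test_constant_trace_has_no_usable_segment(self):
        with pytest.warns(UserWarning, match="constant-width"):
            with pytest.raises(ValueError, match="no usable"):
                fit_deflation_time(flat_trace(n=200), FiringSequence(np.array([])))

    def test_whole_trace_used_when_no_events(self):
        seq = FiringSequence(np.array([]))
        tr = synth_width_trace(seq, tau=0.9, dt=0.02, noise_sd=0.0, t_end=5.0)
        fit = fit_deflation_time(tr, seq)
        assert fit.n_segments == 1
        assert fit.tau_hat == pytest.approx(0.9, rel=1e-6)

    def test_tau_uncorrelated_with_adjacent_interval(self):
        """Per-segment tau estimates do not track the neighbouring firing
        interval: tau is a trap constant, interval fluctuations come from
        the threshold."""
        p = TrapParameters(tau=1.2, x_mean=0.5, x_sd=0.06, seed=33)
        seq, _ = simulate_trap(p, 48.0)
        assert len(seq) >= 51
        seq = FiringSequence(seq.event_times[:51])
        tr = synth_width_trace(seq, tau=1.2, dt=0.01, noise_sd=1.2, seed=34)
        fit = fit_deflation_time(tr, seq)
        taus = np.array(fit.segment_taus[:50])
        durations = np.array(fit.segment_durations[:50])
        rho = np.corrcoef(taus, durations)[0, 1]
        assert abs(rho) < 0.2


class TestInferPressureRatio:
    def test_inverse_identity(self):
        assert infer_pressure_ratio(np.log(2.0) * 1.3, 1.3) == pytest.approx(0.5)

    def test_small_interval_limit(self):
        assert infer_pressure_ratio(1e-9, 1.0) == pytest.approx(0.0, abs=1e-8)

    def test_late_firing_means_nearly_full_deflation(self):
        assert infer_pressure_ratio(5.0, 1.0) == pytest.approx(0.9933, abs=1e-4)


class TestClassifyTrap:
    def test_metronomic_from_near_constant_intervals(self):
        rng = np.random.default_rng(0)
        iv = 1.0 + rng.normal(0, 0.02, 50)
        events = FiringSequence(np.concatenate(([0.0], np.cumsum(iv))))
        s = classify_trap(events, 1.5, horizon=60.0)
        assert s.label == "metronomic"
        assert s.r < 0.1

    def test_waiting_needs_a_long_enough_horizon(self):
        empty = FiringSequence(np.array([]))
        assert classify_trap(empty, 1.0, horizon=10.0).label == "waiting"
        assert classify_trap(empty, 1.0, horizon=3.0).label == "insufficient-data"

    def test_random_from_exponential_train(self):
        iv = np.random.default_rng(1).exponential(4.0, 60)
        events = FiringSequence(np.concatenate(([0.0], np.cumsum(iv))))
        s = classify_trap(events, 1.0, horizon=400.0)
        assert s.label == "random"
        assert not s.intermediate

    def test_intermediate_flagged_as_random(self):
        rng = np.random.default_rng(2)
        iv = 1.0 + np.abs(rng.normal(0, 0.3, 60))
        events = FiringSequence(np.concatenate(([0.0], np.cumsum(iv))))
        s = classify_trap(events, 1.0, horizon=100.0)
        assert s.label == "random"
        assert s.intermediate

    def test_bursting_from_trap_d_like_train(self):
        """Groups of 3-4 regular fast firings separated by long scattered
        gaps classify as bursting."""
        p = TrapParameters(
            tau=1.0, x_mean=0.97, x_sd=0.02, burst_enabled=True,
            x_intra=0.4, x_intra_sd=0.01, tau_r=1.7, seed=5,
        )
        seq, _ = simulate_trap(p, 120.0)
        bursts = segment_bursts(seq)
        s = classify_trap(seq, 1.0, horizon=120.0, bursts=bursts)
        assert s.label == "bursting"

    def test_regime_recovery_on_seeded_cohorts(self):
        """Classification recovers the generating regime on >= 90% of
        traps across 20 seeded four-regime cohorts."""
        hits = total = 0
        for seed in range(20):
            members = make_cohort(
                ["metronomic", "random", "bursting", "waiting"],
                seed=seed, make_traces=False,
            )
            for m in members:
                bursts = segment_bursts(m.seq) if len(m.seq) else None
                s = classify_trap(m.seq, m.params.tau, m.horizon, bursts=bursts)
                hits += s.label == m.label
                total += 1
        assert hits / total >= 0.9
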