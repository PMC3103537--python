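"""Measurement pipeline on width traces and firing-event lists.

Implements the quantities the trap recordings are reduced to: firing
detection on a width trace, the randomness index of an interval train,
the deflation time constant fitted segment-by-segment, the inferred
pressure ratio, and the regime classification
(metronomic / random / bursting / waiting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .burst_analysis import BurstSet
from .simulator import FiringSequence, WidthTrace

__all__ = [
    "DeflationFit",
    "TrapSummary",
    "detect_firings",
    "randomness_index",
    "fit_deflation_time",
    "infer_pressure_ratio",
    "classify_trap",
]


@dataclass(frozen=True)
class DeflationFit:
    """Pooled exponential-deflation fit over inter-firing segments.

    ``tau_hat`` is the mean of per-segment time constants (hours),
    ``tau_se`` the standard error from the per-segment scatter.
    """

    tau_hat: float
    tau_se: float
    w_inf_hat: float
    w_def_hat: float
    n_segments: int
    segment_taus: tuple[float, ...] = ()
    segment_durations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.tau_hat > 0:
            raise ValueError("tau_hat must be > 0")
        if not self.w_inf_hat > self.w_def_hat:
            raise ValueError("w_inf_hat must exceed w_def_hat")


@dataclass(frozen=True)
class TrapSummary:
    """Per-trap reduction: randomness index, mean interval, regime label."""

    r: float
    T_mean: float
    ratio: float
    label: str
    n_events: int
    intermediate: bool = False


def detect_firings(
    trace: WidthTrace,
    jump_frac: float = 0.15,
    refractory_samples: int = 3,
    noise_floor_sigmas: float = 6.0,
) -> FiringSequence:
    """Locate firings as sudden upward width jumps.

    An event is called at each sample where the width increases by more
    than ``jump_frac`` times the robust width range (2.5th-97.5th
    percentile span) within one step; further calls are suppressed for
    ``refractory_samples`` samples.  The threshold is floored at
    ``noise_floor_sigmas`` times the robust step-to-step scatter
    (MAD-based), so that on plateau-dominated traces — where the
    percentile span collapses to the noise scale — measurement noise is
    not mistaken for events.  Flat or too-short traces yield an empty
    sequence, not an error.
    """
    if len(trace) < 3:
        return FiringSequence(np.array([]))
    w = trace.widths
    robust_range = float(np.percentile(w, 97.5) - np.percentile(w, 2.5))
    if robust_range <= 0:
        return FiringSequence(np.array([]))
    jumps = np.diff(w)
    step_sigma = 1.4826 * float(np.median(np.abs(jumps - np.median(jumps))))
    threshold = max(jump_frac * robust_range, noise_floor_sigmas * step_sigma)
    candidates = np.flatnonzero(jumps > threshold)
    events: list[float] = []
    last = -np.inf
    for i in candidates:
        if i - last <= refractory_samples:
            continue
        events.append(trace.times[i + 1])  # the first inflated sample
        last = i
    return FiringSequence(np.array(events))


def randomness_index(intervals) -> float:
    """Drift-robust irregularity r = <|T_{i+1} - T_i|> / <T_i>.

    Successive differences discount slow period drift, so a metronomic
    trap with a drifting period still scores r << 1 while an i.i.d.
    exponential train scores r ~ 1.  Requires at least two intervals.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise ValueError("randomness index needs at least 2 intervals")
    return float(np.mean(np.abs(np.diff(intervals))) / np.mean(intervals))


def _exp_decay(t, w_def, w_inf, tau):
    return w_def + (w_inf - w_def) * np.exp(-t / tau)


def fit_deflation_time(
    trace: WidthTrace,
    events: FiringSequence,
    min_samples: int = 10,
) -> DeflationFit:
    """Fit w(t) = w_def + (w_inf - w_def)*exp(-t/tau) per segment.

    Segments run from each firing to the next (and from the last firing
    to the end of the trace); with no events the whole trace is one
    segment.  All three parameters are free, initialized at
    w_inf = segment max, w_def = segment min, tau = time to 1/e of the
    range.  Degenerate or non-convergent segments are skipped with a
    warning; the pooled tau_hat is the per-segment mean with its standard
    error from the scatter.
    """
    if len(events):
        starts = list(events.event_times)
        ends = list(events.event_times[1:]) + [trace.times[-1] + trace.dt]
    else:
        starts, ends = [trace.times[0]], [trace.times[-1] + trace.dt]

    taus: list[float] = []
    w_infs: list[float] = []
    w_defs: list[float] = []
    durations: list[float] = []
    for t0, t1 in zip(starts, ends):
        mask = (trace.times >= t0) & (trace.times < t1)
        if mask.sum() < min_samples:
            continue
        t_rel = trace.times[mask] - t0
        w = trace.widths[mask]
        w_rng = float(np.ptp(w))
        if w_rng <= 0:
            warnings.warn("constant-width segment skipped", stacklevel=2)
            continue
        w_def0, w_inf0 = float(w.min()), float(w.max())
        below = np.flatnonzero(w <= w_def0 + w_rng / np.e)
        tau0 = float(t_rel[below[0]]) if below.size else float(t_rel[-1] / 3.0)
        tau0 = max(tau0, trace.dt)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _exp_decay, t_rel, w,
                    p0=[w_def0, w_inf0, tau0],
                    bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                    maxfev=10_000,
                )
        except RuntimeError:
            warnings.warn(f"deflation fit did not converge on segment at t={t0:.3f} h",
                          stacklevel=2)
            continue
        w_def_i, w_inf_i, tau_i = map(float, popt)
        if not (tau_i > 0 and w_inf_i > w_def_i):
            warnings.warn(f"unphysical fit discarded on segment at t={t0:.3f} h",
                          stacklevel=2)
            continue
        taus.append(tau_i)
        w_infs.append(w_inf_i)
        w_defs.append(w_def_i)
        durations.append(float(t1 - t0))

    if not taus:
        raise ValueError("no usable deflation segment (all too short or degenerate)")
    taus_arr = np.array(taus)
    se = float(taus_arr.std(ddof=1) / np.sqrt(taus_arr.size)) if taus_arr.size > 1 else 0.0
    return DeflationFit(
        tau_hat=float(taus_arr.mean()),
        tau_se=se,
        w_inf_hat=float(np.mean(w_infs)),
        w_def_hat=float(np.mean(w_defs)),
        n_segments=len(taus),
        segment_taus=tuple(taus),
        segment_durations=tuple(durations),
    )


def infer_pressure_ratio(T_mean: float, tau: float) -> float:
    """First-order estimate x_hat = 1 - exp(-T_mean/tau) of dP_c/dP_max.

    Inverts the mean firing-time law; T_mean >> tau pushes x_hat towards
    1 (firing close to full deflation, the random regime).
    """
    if not (T_mean > 0 and tau > 0):
        raise ValueError("T_mean and tau must be > 0")
    return float(-np.expm1(-T_mean / tau))


def classify_trap(
    events: FiringSequence,
    fit: "DeflationFit | float",
    horizon: float,
    bursts: BurstSet | None = None,
    r_metronomic: float = 0.1,
    r_random: float = 0.5,
    waiting_window: float = 5.0,
    burst_r_max: float = 0.2,
    burst_gap_ratio: float = 3.0,
) -> TrapSummary:
    """Assign one of the four firing regimes to a trap.

    ``fit`` may be a :class:`DeflationFit` or a bare tau (hours).  Rules:
    zero events over a horizon of at least ``waiting_window * tau`` is
    *waiting* (shorter horizons are *insufficient-data*); *bursting*
    requires at least two bursts of two or more firings with regular
    intra-burst intervals (r < ``burst_r_max``) well separated from the
    gaps (gap/intra ratio > ``burst_gap_ratio``); otherwise r below
    ``r_metronomic`` is *metronomic* and r at or above ``r_random`` is
    *random*; in-between traps are reported as random with the
    ``intermediate`` flag set.
    """
    tau_hat = fit.tau_hat if isinstance(fit, DeflationFit) else float(fit)
    if not tau_hat > 0:
        raise ValueError("tau must be > 0")
    nan = float("nan")
    n = len(events)
    if n < 3:  # fewer than two intervals: no randomness index
        if n == 0 and horizon >= waiting_window * tau_hat:
            return TrapSummary(nan, nan, nan, "waiting", 0)
        return TrapSummary(nan, nan, nan, "insufficient-data", n)

    intervals = events.intervals
    r = randomness_index(intervals)
    T_mean = float(intervals.mean())
    ratio = T_mean / tau_hat

    if bursts is not None:
        multi = [b for b in bursts.bursts if b.N >= 2]
        if (
            len(multi) >= 2
            and np.isfinite(bursts.intra_r)
            and bursts.intra_r < burst_r_max
            and bursts.mean_gap > burst_gap_ratio * bursts.mean_intra
        ):
            return TrapSummary(r, T_mean, ratio, "bursting", n)

    if r < r_metronomic:
        return TrapSummary(r, T_mean, ratio, "metronomic", n)
    if r >= r_random:
        return TrapSummary(r, T_mean, ratio, "random", n)
    return TrapSummary(r, T_mean, ratio, "random", n, intermediate=True)
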