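"""Stochastic trap simulator: firing sequences and noisy width traces.

The generator emulates the long time-lapse recordings the model was built
for: a trap fires, its lateral width jumps to the inflated value, then
decays exponentially towards the deflated plateau until the next firing.
The firing interval is governed by the threshold ratio x = dP_c/dP_max,
drawn anew after each firing with gaussian fluctuations:

* ``x`` well below 1 with small sd  -> "metronomic" (near-periodic),
* ``x`` close to 1                  -> "random" (fluctuations amplified),
* ``x`` above 1                     -> "waiting" (no spontaneous firing),
* post-firing excitation that lowers the threshold to ``x_intra`` for a
  relaxation time ``tau_r`` -> "bursting" (trains of fast regular firings
  separated by long scattered gaps).

The excitation is non-retriggerable: it can only re-activate at the first
firing occurring after it has fully relaxed, which bounds the noiseless
burst size at N = 1 + floor(tau_r / T_intra).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import WAITING, firing_time

__all__ = [
    "TrapParameters",
    "FiringSequence",
    "WidthTrace",
    "CohortMember",
    "REGIMES",
    "simulate_trap",
    "synth_width_trace",
    "bursting_sweep",
    "make_cohort",
]

_MAX_EVENTS = 10_000_000  # hard guard against runaway loops


@dataclass(frozen=True)
class TrapParameters:
    """Full stochastic parameterization of one simulated trap.

    ``tau`` deflation time constant (h); ``x_mean``/``x_sd`` mean and sd of
    the threshold ratio; ``burst_enabled`` switches the excitation
    mechanism on, with lowered threshold ``x_intra`` (sd ``x_intra_sd``)
    during the excitation window of duration ``tau_r`` (h).
    ``waiting_redraw`` is the interval (h) after which an over-threshold
    trap re-tests its threshold (defaults to ``tau``, the natural time
    unit).  ``seed`` makes the trap fully reproducible.
    """

    tau: float = 1.0
    x_mean: float = 0.5
    x_sd: float = 0.01
    burst_enabled: bool = False
    x_intra: float = 0.45
    x_intra_sd: float = 0.01
    tau_r: float = 1.7
    waiting_redraw: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.x_sd < 0 or self.x_intra_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.x_mean > 0:
            raise ValueError("x_mean must be > 0")
        if self.waiting_redraw is not None and not self.waiting_redraw > 0:
            raise ValueError("waiting_redraw must be > 0")
        if self.burst_enabled:
            if not 0 < self.x_intra < self.x_mean:
                raise ValueError("bursting requires 0 < x_intra < x_mean")
            if not self.tau_r > 0:
                raise ValueError("bursting requires tau_r > 0")

    @property
    def waiting_redraw_h(self) -> float:
        return self.tau if self.waiting_redraw is None else self.waiting_redraw


@dataclass(frozen=True)
class FiringSequence:
    """Ordered spontaneous-firing times (hours) of one trap."""

    event_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("event_times must be one-dimensional")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        object.__setattr__(self, "event_times", times)

    @property
    def intervals(self) -> np.ndarray:
        """Consecutive inter-firing intervals T_i (hours)."""
        return np.diff(self.event_times)

    def __len__(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class WidthTrace:
    """Uniformly sampled lateral-width series (times in h, widths in um)."""

    times: np.ndarray
    widths: np.ndarray
    dt: float
    noise_sd: float = float("nan")

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        widths = np.asarray(self.widths, dtype=float)
        if times.shape != widths.shape or times.ndim != 1:
            raise ValueError("times and widths must be 1-d arrays of equal length")
        if times.size >= 2 and not np.allclose(np.diff(times), self.dt, rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform with step dt")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "widths", widths)

    def __len__(self) -> int:
        return self.times.size


def _draw_ratio(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One gaussian threshold-ratio draw, redrawn while non-positive.

    Redraw (not clamp) avoids a point mass at instantaneous firing.
    """
    if sd == 0.0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if x > 0.0:
            return x


def simulate_trap(
    p: TrapParameters,
    horizon: float,
    rng: np.random.Generator | None = None,
) -> tuple[FiringSequence, pd.DataFrame]:
    """Simulate one trap over ``horizon`` hours.

    Returns the firing sequence plus a per-event state log with columns
    ``time_h`` (firing time), ``x`` (ratio in force at that firing),
    ``intra`` (fired under excitation) and ``waits`` (number of
    waiting-state redraws preceding it).

    Cycle: after each firing draw x ~ N(x_mean, x_sd) (redraw if <= 0);
    if x >= 1 the trap waits ``waiting_redraw`` hours and redraws (the
    pressure is saturated, only threshold fluctuations can end the wait);
    otherwise it fires after T = -tau*ln(1-x).  With bursting enabled, a
    firing with no active excitation opens an excitation window of length
    ``tau_r`` during which draws use (x_intra, x_intra_sd); a firing
    belongs to the burst only if it lands inside the window, and the
    window can re-open only at the first firing after full relaxation.
    Fully deterministic for a fixed seed.
    """
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    if rng is None:
        rng = np.random.default_rng(p.seed)

    t = 0.0
    window_end = -np.inf  # end of the current excitation window
    times: list[float] = []
    log: list[dict] = []

    while len(times) < _MAX_EVENTS:
        fired = False
        if p.burst_enabled and t < window_end:
            x = _draw_ratio(rng, p.x_intra, p.x_intra_sd)
            if x < 1.0:
                t_cand = t + firing_time(x, p.tau)
                if t_cand <= window_end:
                    # crossing happens while the threshold is still lowered
                    if t_cand > horizon:
                        break
                    times.append(t_cand)
                    log.append({"time_h": t_cand, "x": x, "intra": True, "waits": 0})
                    t = t_cand
                    fired = True
            # else: the window relaxes before the lowered threshold is
            # reached; the ambient threshold takes over from the same
            # firing time (the pressure kept rising throughout).
        if fired:
            continue

        waits = 0
        while True:
            x = _draw_ratio(rng, p.x_mean, p.x_sd)
            if x < 1.0:
                break
            t += p.waiting_redraw_h
            waits += 1
            if t > horizon:
                return FiringSequence(np.array(times)), pd.DataFrame(
                    log, columns=["time_h", "x", "intra", "waits"]
                )
        t_cand = t + firing_time(x, p.tau)
        if t_cand > horizon:
            break
        times.append(t_cand)
        log.append({"time_h": t_cand, "x": x, "intra": False, "waits": waits})
        if p.burst_enabled and t_cand >= window_end:
            window_end = t_cand + p.tau_r  # excitation (re-)activates
        t = t_cand

    return FiringSequence(np.array(times)), pd.DataFrame(
        log, columns=["time_h", "x", "intra", "waits"]
    )


def synth_width_trace(
    seq: FiringSequence,
    tau: float,
    w_inf: float = 600.0,
    w_def: float = 480.0,
    dt: float = 0.02,
    noise_sd: float = 1.2,
    seed: int = 0,
    t_end: float | None = None,
) -> WidthTrace:
    """Render a firing sequence as a noisy lateral-width trace.

    Between firings the noiseless width decays as
    w(t) = w_def + (w_inf - w_def) * exp(-(t - t_fire)/tau) and jumps back
    to ``w_inf`` at each firing (the trace starts inflated at t = 0).
    Additive gaussian measurement noise of sd ``noise_sd`` is truncated at
    +-5 sd so widths stay within the physical band.  ``dt`` must resolve
    the fastest firings (dt < min interval / 5).
    """
    if not w_inf > w_def:
        raise ValueError("w_inf must exceed w_def")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    intervals = seq.intervals
    if intervals.size and dt >= intervals.min() / 5.0:
        raise ValueError(
            f"dt={dt} too coarse: firings {intervals.min():.4f} h apart "
            "would be unresolvable (need dt < min interval / 5)"
        )
    if t_end is None:
        t_end = (seq.event_times[-1] if len(seq) else 0.0) + 3.0 * tau
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    # time since the last firing (the trace starts inflated at t=0)
    anchors = np.concatenate(([0.0], seq.event_times))
    idx = np.searchsorted(anchors, times, side="right") - 1
    elapsed = times - anchors[idx]
    widths = w_def + (w_inf - w_def) * np.exp(-elapsed / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.clip(rng.normal(0.0, noise_sd, size=times.size),
                        -5.0 * noise_sd, 5.0 * noise_sd)
        widths = widths + noise
    return WidthTrace(times=times, widths=widths, dt=dt, noise_sd=noise_sd)


# Default parameter ranges per regime.  These are the study conditions the
# generator emulates: metronomic traps fire every 1-3 h at an early stage
# of deflation; random traps fire close to full deflation (x near 1, mean
# interval > 5 h once waiting spells are included); waiting traps sit just
# above threshold; bursting traps combine a near-1 ambient threshold with
# a lowered intra-burst threshold and an excitation time of order 1-2.4 h,
# giving 15 min - 1 h intra-burst intervals.
REGIMES: dict[str, dict] = {
    "metronomic": dict(tau=(1.5, 2.5), x_mean=(0.45, 0.60), x_sd=0.01),
    "random": dict(tau=(1.0, 2.0), x_mean=(0.95, 0.99), x_sd=0.04),
    "waiting": dict(tau=(1.0, 2.0), x_mean=(1.05, 1.20), x_sd=0.01),
    "bursting": dict(
        tau=(0.8, 1.2), x_mean=(0.95, 0.99), x_sd=0.02,
        x_intra=(0.35, 0.60), x_intra_sd=0.01, tau_r=(1.2, 2.4),
    ),
}

_HORIZONS = {"metronomic": 72.0, "random": 240.0, "waiting": 72.0, "bursting": 120.0}


@dataclass(frozen=True)
class CohortMember:
    """One labelled synthetic trap: parameters, events and width trace."""

    label: str
    params: TrapParameters
    seq: FiringSequence
    trace: WidthTrace | None
    horizon: float
    log: pd.DataFrame = field(repr=False, default=None)


def _sample_regime_params(
    label: str, rng: np.random.Generator, overrides: dict | None
) -> TrapParameters:
    if label not in REGIMES:
        raise ValueError(f"unknown regime label {label!r}; known: {sorted(REGIMES)}")
    spec = dict(REGIMES[label])
    kwargs: dict = {"burst_enabled": label == "bursting"}
    for key, val in spec.items():
        kwargs[key] = rng.uniform(*val) if isinstance(val, tuple) else val
    if overrides:
        kwargs.update(overrides)
    kwargs["seed"] = int(kwargs.get("seed", rng.integers(0, 2**31)))
    return TrapParameters(**kwargs)


def bursting_sweep(
    n_traps: int = 40,
    tau: float = 1.0,
    tau_r: float = 1.7,
    T_intra_range: tuple[float, float] = (0.3, 0.85),
    x_mean: float = 0.98,
    x_sd: float = 0.01,
    x_intra_sd: float = 0.005,
    seed: int = 0,
) -> list[TrapParameters]:
    """Bursting cohort whose intra-burst intervals sweep a target range.

    Each trap's lowered threshold is set so that its noiseless
    intra-burst interval equals one value of a uniform grid over
    ``T_intra_range`` (hours), via x_intra = 1 - exp(-T_intra/tau); all
    traps share the same excitation relaxation time ``tau_r``.  This is
    the cohort used to recover tau_r from the burst-size versus
    intra-burst-frequency relation.
    """
    rng = np.random.default_rng(seed)
    targets = np.linspace(*T_intra_range, n_traps)
    return [
        TrapParameters(
            tau=tau, x_mean=x_mean, x_sd=x_sd, burst_enabled=True,
            x_intra=float(-np.expm1(-T / tau)), x_intra_sd=x_intra_sd,
            tau_r=tau_r, seed=int(rng.integers(0, 2**31)),
        )
        for T in targets
    ]


def make_cohort(
    spec: list[str | tuple[str, dict]],
    seed: int = 0,
    make_traces: bool = True,
    noise_frac: float = 0.01,
) -> list[CohortMember]:
    """Build a reproducible labelled cohort of synthetic traps.

    ``spec`` lists regime labels (optionally ``(label, overrides)`` pairs
    to pin parameters); one trap is generated per entry, with parameters
    drawn from the documented per-regime ranges.  Measurement noise on
    the width traces defaults to ``noise_frac`` of the inflation range.
    Identical ``(spec, seed)`` yield bit-identical cohorts.
    """
    if not spec:
        raise ValueError("cohort spec must list at least one regime label")
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for entry in spec:
        label, overrides = entry if isinstance(entry, tuple) else (entry, None)
        params = _sample_regime_params(label, rng, overrides)
        horizon = _HORIZONS.get(label, 120.0)
        seq, log = simulate_trap(params, horizon)
        trace = None
        if make_traces:
            w_inf, w_def = 600.0, 480.0
            min_int = seq.intervals.min() if len(seq) > 1 else np.inf
            dt = min(0.05, min_int / 6.0) if np.isfinite(min_int) else 0.05
            trace = synth_width_trace(
                seq, tau=params.tau, w_inf=w_inf, w_def=w_def, dt=dt,
                noise_sd=noise_frac * (w_inf - w_def),
                seed=int(rng.integers(0, 2**31)), t_end=horizon,
            )
        members.append(CohortMember(label, params, seq, trace, horizon, log))
    return members
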