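"""Analytic propagation of threshold fluctuations to firing intervals.

Gaussian fluctuations of the threshold ratio x = dP_c/dP_max around a
mean x_bar with sd sigma_x map through the firing-time law
T = -tau*ln(1-x) to the interval statistics.  To leading order in the
Taylor expansion (valid while sigma_x/(1-x_bar) stays small):

    <T>     = -tau * ln(1 - x_bar)
    sigma_T =  tau * sigma_x / (1 - x_bar)

The 1/(1-x_bar) denominator is the whole story of the metronomic-random
continuum: the same threshold noise is amplified without bound as the
mean threshold approaches the pumping saturation.  The full interval
density follows by change of variables and is increasingly right-skewed
as x_bar -> 1; the gaussian mass at x >= 1 is the waiting probability
and is reported separately, never renormalized away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .core_model import WAITING, WaitingState, firing_time

__all__ = [
    "TheoryPrediction",
    "IntervalPdf",
    "McSummary",
    "mean_interval",
    "interval_sd",
    "interval_pdf",
    "predict",
    "mc_check",
]

VALIDITY_RATIO_MAX = 0.1
"""Default bound on sigma_x/(1 - x_bar) for the Taylor expansion to hold."""


def _check_inputs(x_mean: float, x_sd: float, tau: float) -> None:
    if not x_mean > 0:
        raise ValueError("x_mean must be > 0")
    if x_sd < 0:
        raise ValueError("x_sd must be >= 0")
    if not tau > 0:
        raise ValueError("tau must be > 0")


def _is_valid(x_mean: float, x_sd: float, threshold: float) -> bool:
    return x_sd / (1.0 - x_mean) <= threshold


def mean_interval(
    x_mean: float, x_sd: float, tau: float,
    validity_threshold: float = VALIDITY_RATIO_MAX,
) -> tuple[float | WaitingState, bool]:
    """First-order mean interval <T> = -tau*ln(1 - x_mean), with validity.

    The flag is True when sigma_x/(1 - x_mean) <= ``validity_threshold``,
    the proxy for the expansion conditions (the second-order correction
    being negligible is the more restrictive one).  x_mean >= 1 returns
    the WAITING sentinel (flag False).
    """
    _check_inputs(x_mean, x_sd, tau)
    if x_mean >= 1.0:
        return WAITING, False
    return firing_time(x_mean, tau), _is_valid(x_mean, x_sd, validity_threshold)


def interval_sd(x_mean: float, x_sd: float, tau: float) -> float | WaitingState:
    """Leading-order interval sd sigma_T = tau*sigma_x/(1 - x_mean).

    Assumes a symmetric x distribution (odd Taylor terms vanish).
    Diverges as x_mean -> 1: threshold fluctuations are amplified near
    the pumping saturation.  x_mean >= 1 returns WAITING.
    """
    _check_inputs(x_mean, x_sd, tau)
    if x_mean >= 1.0:
        return WAITING
    return tau * x_sd / (1.0 - x_mean)


@dataclass(frozen=True)
class IntervalPdf:
    """Exact firing-interval density under gaussian threshold noise.

    Change of variables through T = -tau*ln(1-x):
    p_T(T) = N(1 - e^{-T/tau}; x_mean, x_sd) * e^{-T/tau} / tau for T > 0.
    ``trunc_mass`` is the gaussian probability of x >= 1 (waiting); the
    density is *not* renormalized, so integral + trunc_mass accounts for
    all mass except the (normally negligible) tail at x <= 0.
    """

    x_mean: float
    x_sd: float
    tau: float

    def __call__(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        decay = np.exp(-np.clip(T, 0.0, None) / self.tau)
        x = 1.0 - decay
        dens = stats.norm.pdf(x, self.x_mean, self.x_sd) * decay / self.tau
        out = np.where(T > 0, dens, 0.0)
        return float(out) if out.ndim == 0 else out

    @property
    def trunc_mass(self) -> float:
        """Gaussian mass at x >= 1: the probability of a waiting draw."""
        return float(stats.norm.sf(1.0, self.x_mean, self.x_sd))

    def cdf(self, T) -> np.ndarray:
        """P(interval <= T) among all draws (waiting mass never arrives)."""
        T = np.asarray(T, dtype=float)
        x = 1.0 - np.exp(-np.clip(T, 0.0, None) / self.tau)
        out = np.where(
            T > 0,
            stats.norm.cdf(x, self.x_mean, self.x_sd)
            - stats.norm.cdf(0.0, self.x_mean, self.x_sd),
            0.0,
        )
        return float(out) if out.ndim == 0 else out


def interval_pdf(x_mean: float, x_sd: float, tau: float) -> IntervalPdf:
    """Density of firing intervals for gaussian threshold fluctuations."""
    _check_inputs(x_mean, x_sd, tau)
    if not x_sd > 0:
        raise ValueError("interval_pdf requires x_sd > 0 (delta otherwise)")
    return IntervalPdf(x_mean, x_sd, tau)


@dataclass(frozen=True)
class TheoryPrediction:
    """Analytic interval statistics bundle with validity bookkeeping."""

    T_mean: float | WaitingState
    T_sd: float | WaitingState
    valid: bool
    pdf: Callable | None
    trunc_mass: float

    @property
    def waiting(self) -> bool:
        return self.T_mean is WAITING


def predict(
    x_mean: float, x_sd: float, tau: float,
    validity_threshold: float = VALIDITY_RATIO_MAX,
) -> TheoryPrediction:
    """Assemble mean, sd, density and waiting mass for one parameter set."""
    T_mean, valid = mean_interval(x_mean, x_sd, tau, validity_threshold)
    T_sd = interval_sd(x_mean, x_sd, tau)
    pdf = interval_pdf(x_mean, x_sd, tau) if x_sd > 0 else None
    trunc = pdf.trunc_mass if pdf is not None else (1.0 if x_mean >= 1 else 0.0)
    return TheoryPrediction(T_mean, T_sd, valid, pdf, trunc)


@dataclass(frozen=True)
class McSummary:
    """Monte-Carlo oracle output for the analytic predictions."""

    mean: float
    sd: float
    n_used: int
    n_waiting: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    samples: np.ndarray


def mc_check(
    x_mean: float, x_sd: float, tau: float, n: int, seed: int = 0, bins: int = 50
) -> McSummary:
    """Draw ``n`` threshold ratios and report empirical interval statistics.

    Draws with x >= 1 go to the waiting counter (no firing); draws with
    x <= 0 are redrawn as in the simulator.  With x_sd = 0 all intervals
    are identical.
    """
    _check_inputs(x_mean, x_sd, tau)
    if n < 10:
        raise ValueError("n must be >= 10 for a meaningful check")
    rng = np.random.default_rng(seed)
    if x_sd == 0.0:
        x = np.full(n, x_mean)
    else:
        x = rng.normal(x_mean, x_sd, size=n)
        while True:  # redraw the (rare) non-positive draws
            bad = x <= 0
            if not bad.any():
                break
            x[bad] = rng.normal(x_mean, x_sd, size=int(bad.sum()))
    waiting = x >= 1.0
    x_ok = x[~waiting]
    T = -tau * np.log1p(-x_ok)
    counts, edges = np.histogram(T, bins=bins)
    return McSummary(
        mean=float(T.mean()) if T.size else float("nan"),
        sd=float(T.std(ddof=1)) if T.size > 1 else 0.0,
        n_used=int(T.size),
        n_waiting=int(waiting.sum()),
        hist_counts=counts,
        hist_edges=edges,
        samples=T,
    )
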