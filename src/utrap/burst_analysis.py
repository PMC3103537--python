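"""Burst segmentation and recovery of the excitation relaxation time.

Bursting traps emit trains of 2-7 fast, regular firings separated by long
scattered gaps.  The excitation model predicts that the number of firings
per burst grows with the intra-burst firing frequency f = 1/<T_intra> as
N ~ tau_r * f, so the through-origin slope of N versus f across many
bursts estimates the excitation relaxation time tau_r (hours).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulator import FiringSequence

__all__ = ["Burst", "BurstSet", "segment_bursts", "burst_table", "fit_burst_relaxation"]


@dataclass(frozen=True)
class Burst:
    """One burst: the indices and times of its firings (initiator included)."""

    indices: tuple[int, ...]
    times: tuple[float, ...]

    @property
    def N(self) -> int:
        return len(self.times)

    @property
    def intra_intervals(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def T_intra_mean(self) -> float:
        """Mean intra-burst interval (hours); nan for singletons."""
        iv = self.intra_intervals
        return float(iv.mean()) if iv.size else float("nan")

    @property
    def r_intra(self) -> float:
        """Randomness index within the burst; nan below 2 intervals."""
        iv = self.intra_intervals
        if iv.size < 2:
            return float("nan")
        return float(np.mean(np.abs(np.diff(iv))) / iv.mean())


@dataclass(frozen=True)
class BurstSet:
    """Partition of a firing sequence into bursts plus inter-burst gaps."""

    bursts: tuple[Burst, ...]
    gaps: tuple[float, ...]  # last firing of burst i -> first of burst i+1

    @property
    def sizes(self) -> np.ndarray:
        return np.array([b.N for b in self.bursts])

    @property
    def mean_intra(self) -> float:
        iv = self._all_intra()
        return float(iv.mean()) if iv.size else float("nan")

    @property
    def mean_gap(self) -> float:
        return float(np.mean(self.gaps)) if self.gaps else float("nan")

    @property
    def intra_r(self) -> float:
        """Randomness index of the pooled intra-burst intervals.

        Pooled in chronological order across bursts, so it also penalizes
        burst-to-burst drift of the intra interval; nan below 2 intervals.
        """
        iv = self._all_intra()
        if iv.size < 2:
            return float("nan")
        return float(np.mean(np.abs(np.diff(iv))) / iv.mean())

    def _all_intra(self) -> np.ndarray:
        parts = [b.intra_intervals for b in self.bursts if b.N >= 2]
        return np.concatenate(parts) if parts else np.array([])


def segment_bursts(events: FiringSequence, gap_factor: float = 3.0) -> BurstSet:
    """Split a firing sequence into bursts at anomalously long intervals.

    The intra-burst time scale is estimated robustly as the median of the
    intervals at or below the sample median (the lower mode of a bimodal
    interval distribution); a new burst starts wherever an interval
    exceeds ``gap_factor`` times that scale.  With all intervals equal no
    gap qualifies and the whole sequence is one burst.  Singleton bursts
    are allowed.  Idempotent and invariant under uniform time shifts.
    """
    if len(events) == 0:
        raise ValueError("segment_bursts needs at least one event")
    times = events.event_times
    if len(events) == 1:
        return BurstSet((Burst((0,), (float(times[0]),)),), ())

    intervals = events.intervals
    med = float(np.median(intervals))
    lower = intervals[intervals <= med]
    intra_scale = float(np.median(lower))
    threshold = gap_factor * intra_scale

    bursts: list[Burst] = []
    gaps: list[float] = []
    start = 0
    for i, gap in enumerate(intervals):
        if gap > threshold:
            idx = tuple(range(start, i + 1))
            bursts.append(Burst(idx, tuple(float(times[j]) for j in idx)))
            gaps.append(float(gap))
            start = i + 1
    idx = tuple(range(start, len(times)))
    bursts.append(Burst(idx, tuple(float(times[j]) for j in idx)))
    return BurstSet(tuple(bursts), tuple(gaps))


def burst_table(bursts: BurstSet | Iterable[Burst]) -> pd.DataFrame:
    """Per-burst summary table: id, size, start, mean intra interval, r."""
    items = bursts.bursts if isinstance(bursts, BurstSet) else tuple(bursts)
    rows = [
        {
            "burst_id": i,
            "n_events": b.N,
            "t_start_h": b.times[0],
            "T_intra_mean_h": b.T_intra_mean,
            "r_intra": b.r_intra,
        }
        for i, b in enumerate(items)
    ]
    return pd.DataFrame(rows, columns=["burst_id", "n_events", "t_start_h",
                                       "T_intra_mean_h", "r_intra"])


def fit_burst_relaxation(table: "pd.DataFrame | Sequence[tuple[float, float]]") -> float:
    """Excitation relaxation time tau_r (hours) from burst sizes.

    Least-squares slope *through the origin* of burst size N against the
    intra-burst firing frequency f = 1/<T_intra>, per the prediction
    N ~ tau_r * f.  Accepts a dataframe with ``n_events`` and either
    ``f_per_h`` or ``T_intra_mean_h`` columns, or an iterable of
    ``(N, f)`` pairs.  Singleton bursts carry no frequency and are
    excluded; at least two multi-firing bursts are required.
    """
    if isinstance(table, pd.DataFrame):
        n = table["n_events"].to_numpy(dtype=float)
        if "f_per_h" in table.columns:
            f = table["f_per_h"].to_numpy(dtype=float)
        else:
            f = 1.0 / table["T_intra_mean_h"].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(table), dtype=float)
        if pairs.size == 0:
            raise ValueError("need at least 2 bursts with >= 2 firings")
        n, f = pairs[:, 0], pairs[:, 1]
    keep = (n >= 2) & np.isfinite(f) & (f > 0)
    n, f = n[keep], f[keep]
    if n.size < 2:
        raise ValueError("need at least 2 bursts with >= 2 firings to fit tau_r")
    return float(np.sum(n * f) / np.sum(f * f))
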