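"""File formats, configuration and end-to-end orchestration.

External conventions: times in **hours**, widths in **micrometres**,
strict two/one-column CSV dialects (extra columns are rejected to prevent
silent unit mistakes), '.' decimal, UTF-8.  All error paths log at ERROR
before raising; nothing fails silently.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burst_analysis, trace_analysis
from .simulator import CohortMember, FiringSequence, WidthTrace, make_cohort

__all__ = [
    "PipelineFormatError",
    "RunConfig",
    "read_width_trace",
    "write_width_trace",
    "read_events",
    "write_events",
    "write_cohort",
    "read_cohort",
    "analyze_cohort",
    "run_report",
]

logger = logging.getLogger("utrap")

_TRACE_HEADER = ["time_h", "width_um"]
_EVENTS_HEADER = ["time_h"]


class PipelineFormatError(ValueError):
    """A CSV file violated the strict pipeline dialect."""


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    ``seed`` master seed; ``n_per_regime`` cohort size per firing regime;
    ``noise_frac`` width-trace measurement noise as a fraction of the
    inflation range; ``jump_frac``/``refractory_samples`` firing
    detection; ``gap_factor`` burst segmentation; ``r_metronomic``/
    ``r_random`` classification cutoffs (only the metronomic 0.1 is
    anchored in the recorded calibration); ``waiting_window`` horizon in
    units of tau below which an eventless trap is insufficient-data
    rather than waiting; ``validity_ratio_max`` Taylor-validity proxy
    bound sigma_x/(1-x_mean).
    """

    seed: int = 0
    n_per_regime: int = 5
    noise_frac: float = 0.01
    jump_frac: float = 0.15
    refractory_samples: int = 3
    gap_factor: float = 3.0
    r_metronomic: float = 0.1
    r_random: float = 0.5
    waiting_window: float = 5.0
    validity_ratio_max: float = 0.1

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.n_per_regime < 1:
            raise ValueError("n_per_regime must be >= 1")
        for name in ("noise_frac", "jump_frac", "gap_factor", "r_metronomic",
                     "r_random", "waiting_window", "validity_ratio_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.refractory_samples < 0:
            raise ValueError("refractory_samples must be >= 0")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            logger.error("unknown config keys: %s", sorted(unknown))
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            logger.error("config %s is not a mapping", path)
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)


def _read_strict_csv(path: str | Path, header: list[str]) -> np.ndarray:
    """Read a strict numeric CSV, reporting the offending line on error."""
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            first = next(reader)
        except StopIteration:
            logger.error("%s: empty file, expected header %s", path, header)
            raise PipelineFormatError(f"{path}: line 1: missing header {header}")
        if first != header:
            logger.error("%s: bad header %r", path, first)
            raise PipelineFormatError(
                f"{path}: line 1: expected header {','.join(header)!r}, got {','.join(first)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                logger.error("%s: line %d has %d columns", path, lineno, len(row))
                raise PipelineFormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(row)}"
                )
            try:
                rows.append([float(cell) for cell in row])
            except ValueError:
                logger.error("%s: line %d non-numeric", path, lineno)
                raise PipelineFormatError(
                    f"{path}: line {lineno}: non-numeric cell in {row!r}"
                ) from None
    return np.array(rows, dtype=float).reshape(len(rows), len(header))


def read_width_trace(path: str | Path) -> WidthTrace:
    """Read a ``time_h,width_um`` CSV into a :class:`WidthTrace`.

    Times must be strictly increasing and uniformly sampled; the round
    trip through :func:`write_width_trace` is lossless in value.
    """
    data = _read_strict_csv(path, _TRACE_HEADER)
    if data.shape[0] < 2:
        logger.error("%s: need at least 2 samples", path)
        raise PipelineFormatError(f"{path}: need at least 2 samples")
    times, widths = data[:, 0], data[:, 1]
    steps = np.diff(times)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 3  # header + 1-based + next row
        logger.error("%s: non-monotone time at line %d", path, bad)
        raise PipelineFormatError(f"{path}: line {bad}: time_h not strictly increasing")
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-12):
        logger.error("%s: non-uniform sampling", path)
        raise PipelineFormatError(f"{path}: sampling step is not uniform")
    return WidthTrace(times=times, widths=widths, dt=dt)


def write_width_trace(trace: WidthTrace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRACE_HEADER)
        for t, w in zip(trace.times, trace.widths):
            writer.writerow([repr(float(t)), repr(float(w))])


def read_events(path: str | Path) -> FiringSequence:
    """Read a ``time_h`` CSV of firing times (may be empty past the header)."""
    data = _read_strict_csv(path, _EVENTS_HEADER)
    times = data[:, 0] if data.size else np.array([])
    if times.size > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 3
        logger.error("%s: non-increasing event time at line %d", path, bad)
        raise PipelineFormatError(
            f"{path}: line {bad}: event times must be strictly increasing (no duplicates)"
        )
    return FiringSequence(times)


def write_events(seq: FiringSequence, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENTS_HEADER)
        for t in seq.event_times:
            writer.writerow([repr(float(t))])


def write_cohort(members: list[CohortMember], outdir: str | Path) -> Path:
    """Write cohort fixtures (events + traces + manifest) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, m in enumerate(members):
        trap_id = f"trap{i:03d}"
        events_file = f"{trap_id}_events.csv"
        write_events(m.seq, outdir / events_file)
        trace_file = ""
        if m.trace is not None:
            trace_file = f"{trap_id}_trace.csv"
            write_width_trace(m.trace, outdir / trace_file)
        rows.append({
            "trap_id": trap_id,
            "label": m.label,
            "tau_true_h": m.params.tau,
            "horizon_h": m.horizon,
            "events_file": events_file,
            "trace_file": trace_file,
        })
    manifest = outdir / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    logger.info("wrote %d traps to %s", len(members), outdir)
    return manifest


def read_cohort(indir: str | Path) -> pd.DataFrame:
    """Load a cohort manifest and its fixtures back from disk."""
    indir = Path(indir)
    manifest = indir / "cohort.csv"
    if not manifest.exists():
        logger.error("no cohort manifest at %s", manifest)
        raise FileNotFoundError(f"no cohort manifest at {manifest}")
    table = pd.read_csv(manifest, keep_default_na=False)
    table["seq"] = [read_events(indir / f) for f in table["events_file"]]
    table["trace"] = [
        read_width_trace(indir / f) if f else None for f in table["trace_file"]
    ]
    return table


def analyze_cohort(cohort: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Run the full measurement chain on a loaded cohort.

    For each trap: detect firings on the trace (falling back to the
    stored event list when no trace exists), fit the deflation time,
    segment bursts and classify the regime.  Returns one summary row per
    trap: n_events, T_mean_h, r, tau_hat_h, ratio, label, intermediate.
    """
    cfg = config or RunConfig()
    rows = []
    for rec in cohort.itertuples():
        trace: WidthTrace | None = rec.trace
        if trace is not None:
            events = trace_analysis.detect_firings(
                trace, jump_frac=cfg.jump_frac,
                refractory_samples=cfg.refractory_samples,
            )
            try:
                fit = trace_analysis.fit_deflation_time(trace, events)
                tau_src: trace_analysis.DeflationFit | float = fit
                tau_hat = fit.tau_hat
            except ValueError:
                logger.warning("%s: no usable deflation segment, using nominal tau",
                               rec.trap_id)
                tau_src = float(rec.tau_true_h)
                tau_hat = float(rec.tau_true_h)
        else:
            events = rec.seq
            tau_src = float(rec.tau_true_h)
            tau_hat = float(rec.tau_true_h)
        bursts = (
            burst_analysis.segment_bursts(events, gap_factor=cfg.gap_factor)
            if len(events) else None
        )
        summary = trace_analysis.classify_trap(
            events, tau_src, horizon=float(rec.horizon_h), bursts=bursts,
            r_metronomic=cfg.r_metronomic, r_random=cfg.r_random,
            waiting_window=cfg.waiting_window,
        )
        rows.append({
            "trap_id": rec.trap_id,
            "label_true": rec.label,
            "n_events": summary.n_events,
            "T_mean_h": summary.T_mean,
            "r": summary.r,
            "tau_hat_h": tau_hat,
            "ratio": summary.ratio,
            "label": summary.label,
            "intermediate": summary.intermediate,
        })
    return pd.DataFrame(rows)


def run_report(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Full chain: simulate -> write -> read -> analyze -> report.

    Writes cohort fixtures, the per-trap summary table and the per-burst
    table (with the fitted excitation time when enough bursts exist).
    Byte-identical outputs under a fixed (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = ["metronomic", "random", "bursting", "waiting"]
    spec = [lab for lab in labels for _ in range(config.n_per_regime)]
    members = make_cohort(spec, seed=config.seed, noise_frac=config.noise_frac)
    fixtures = outdir / "cohort"
    write_cohort(members, fixtures)

    cohort = read_cohort(fixtures)
    summary = analyze_cohort(cohort, config)
    summary_path = outdir / "trap_summary.csv"
    summary.to_csv(summary_path, index=False)

    burst_rows = []
    pairs: list[tuple[float, float]] = []
    for rec in cohort.itertuples():
        if len(rec.seq) == 0:
            continue
        bursts = burst_analysis.segment_bursts(rec.seq, gap_factor=config.gap_factor)
        tab = burst_analysis.burst_table(bursts)
        tab.insert(0, "trap_id", rec.trap_id)
        burst_rows.append(tab)
        for b in bursts.bursts:
            if b.N >= 2:
                pairs.append((b.N, 1.0 / b.T_intra_mean))
    bursts_path = outdir / "bursts.csv"
    burst_df = (
        pd.concat(burst_rows, ignore_index=True) if burst_rows else pd.DataFrame()
    )
    burst_df.to_csv(bursts_path, index=False)

    tau_r_path = outdir / "tau_r.txt"
    try:
        tau_r = burst_analysis.fit_burst_relaxation(pairs)
        tau_r_path.write_text(f"tau_r_hat_h,{tau_r!r}\n", encoding="utf-8")
    except ValueError:
        logger.warning("too few multi-firing bursts to fit tau_r")
        tau_r_path.write_text("tau_r_hat_h,nan\n", encoding="utf-8")

    logger.info("report written to %s", outdir)
    return {"summary": summary_path, "bursts": bursts_path, "tau_r": tau_r_path}
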