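"""Fiber-photometry processing.

ΔF/F is the pointwise fractional change relative to the mean fluorescence in
a baseline window (by convention the 50 s immediately before the alignment
event); the Z-score uses the same window's mean and SD, so baseline samples
have mean 0 and SD 1 by construction.  Peri-event alignment stacks Z-scored
windows around repeated events (trial × time, with the event at offset 0) for
peak-amplitude and peak-time statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default baseline window length (s) before the alignment event.
DEFAULT_BASELINE_S = 50.0


@dataclass
class PhotometryTrace:
    """Uniformly sampled raw fluorescence with named event markers (s)."""

    times: np.ndarray
    f_raw: np.ndarray
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        if self.times.size != self.f_raw.size:
            raise ValueError("times and f_raw must have equal length")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("photometry trace must be uniformly sampled")
        if not np.all(np.isfinite(self.f_raw)):
            raise ValueError("fluorescence values must be finite")

    @property
    def rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class DffTrace:
    times: np.ndarray
    values: np.ndarray  # dimensionless ΔF/F
    baseline: tuple[float, float]
    baseline_mean: float
    baseline_sd: float


@dataclass
class ZTrace:
    times: np.ndarray
    values: np.ndarray  # baseline-SD units
    baseline: tuple[float, float]
    baseline_mean: float
    baseline_sd: float

    @property
    def rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class PeriEventTensor:
    """Event-aligned Z-score windows: rows are trials, columns share one time
    axis of offsets relative to the event (offset 0 is the event sample)."""

    offsets: np.ndarray  # s, includes 0
    data: np.ndarray  # (n_trials, n_samples)
    event_label: str
    window: tuple[float, float]  # (pre, post) s

    def mean_trace(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class PeakStats:
    peak_z: float
    peak_time: float  # s relative to the event


def _baseline_stats(trace: PhotometryTrace, baseline: tuple[float, float]):
    start, end = baseline
    if end <= start:
        raise ValueError("baseline window is empty")
    mask = (trace.times >= start) & (trace.times < end)
    if mask.sum() < 2:
        raise ValueError("baseline window lies outside the record")
    vals = trace.f_raw[mask]
    return float(vals.mean()), float(vals.std(ddof=0)), mask


def compute_dff(trace: PhotometryTrace, baseline: tuple[float, float]) -> DffTrace:
    """ΔF/F(t) = (F(t) − F̄) / F̄ with F̄ the baseline-window mean."""
    mu, sd, _ = _baseline_stats(trace, baseline)
    if mu <= 0:
        raise ValueError("baseline mean fluorescence must be positive for ΔF/F")
    return DffTrace(
        times=trace.times,
        values=(trace.f_raw - mu) / mu,
        baseline=baseline,
        baseline_mean=mu,
        baseline_sd=sd,
    )


def compute_zscore(trace: PhotometryTrace, baseline: tuple[float, float]) -> ZTrace:
    """Z(t) = (F(t) − μ) / σ with μ, σ from the baseline window."""
    mu, sd, _ = _baseline_stats(trace, baseline)
    if sd <= 0:
        raise ValueError("baseline SD must be positive for Z-scoring")
    return ZTrace(
        times=trace.times,
        values=(trace.f_raw - mu) / sd,
        baseline=baseline,
        baseline_mean=mu,
        baseline_sd=sd,
    )


def align_peri_event(
    ztrace: ZTrace,
    events: list[float] | np.ndarray,
    pre: float = 50.0,
    post: float = 300.0,
    event_label: str = "event",
) -> PeriEventTensor:
    """Stack Z-score windows of (pre, post) seconds around each event.

    Windows run from −pre to +post inclusive (length pre·fs + post·fs + 1
    samples); events without full window coverage are dropped with a logged
    warning.
    """
    events = np.atleast_1d(np.asarray(events, dtype=float))
    if events.size == 0:
        raise ValueError("event list is empty")
    fs = ztrace.rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    offsets = np.arange(-n_pre, n_post + 1) / fs

    rows = []
    for ev in events:
        idx = int(round((ev - ztrace.times[0]) * fs))
        lo, hi = idx - n_pre, idx + n_post + 1
        if lo < 0 or hi > ztrace.values.size:
            logger.warning("event at %.3f s lacks full window coverage; dropped", ev)
            continue
        rows.append(ztrace.values[lo:hi])
    if not rows:
        raise ValueError("no event has full window coverage")
    return PeriEventTensor(
        offsets=offsets,
        data=np.vstack(rows),
        event_label=event_label,
        window=(pre, post),
    )


def peak_stats(
    tensor: PeriEventTensor, search: tuple[float, float]
) -> list[PeakStats]:
    """Per-trial peak Z and its time within the search window.

    Ties are broken toward the earliest time (argmax convention).
    """
    lo, hi = search
    half_sample = 0.5 * (tensor.offsets[1] - tensor.offsets[0]) if tensor.offsets.size > 1 else 0.0
    if lo < tensor.offsets[0] - half_sample or hi > tensor.offsets[-1] + half_sample:
        raise ValueError("search window must lie within the aligned window")
    mask = (tensor.offsets >= lo) & (tensor.offsets <= hi)
    out = []
    for row in tensor.data:
        seg = row[mask]
        if np.all(np.isnan(seg)):
            raise ValueError("all-NaN trial row in search window")
        i = int(np.nanargmax(seg))
        out.append(PeakStats(peak_z=float(seg[i]), peak_time=float(tensor.offsets[mask][i])))
    return out
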