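"""Righting-reflex latency extraction, per-animal summaries and group tests.

The righting test flips the cage every 15 s: LORR (loss of righting reflex)
is the first failed righting after anesthetic onset, RORR (recovery) the
first successful righting after cessation, both reported as latencies from
the respective marker.  Per-animal summaries collect the quantities the
downstream comparisons use: core temperature at fixed protocol times, LORR/
RORR, overall BSR over the maintenance window, and mean relative band powers
for maintenance (0–30 min) and recovery (cessation to RORR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .eeg import compute_band_powers, compute_bsr, detect_suppressions, BANDS

logger = logging.getLogger(__name__)

MAINTENANCE_WINDOW = (0.0, 30.0 * 60.0)  # s


@dataclass
class RightingEvents:
    """Flip-test log: times (s, same axis as the recording) and outcomes
    ('success' = animal rights itself, 'fail' = righting reflex absent)."""

    times: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=object)
        if self.times.size != self.outcomes.size:
            raise ValueError("times and outcomes must have equal length")
        bad = set(np.unique(self.outcomes)) - {"success", "fail"}
        if bad:
            raise ValueError(f"unknown outcomes: {sorted(bad)}")


def extract_lorr_rorr(
    log: RightingEvents, iso_start: float, iso_stop: float
) -> tuple[float, float]:
    """LORR and RORR latencies (s) from a flip log.

    LORR = time of the first failed righting at/after ``iso_start`` minus
    ``iso_start``; RORR = time of the first successful righting at/after
    ``iso_stop`` minus ``iso_stop``.  Raises if either event is absent —
    a truncated log is an error, never a silent zero.
    """
    order = np.argsort(log.times, kind="stable")
    times, outcomes = log.times[order], log.outcomes[order]

    fail_after = times[(times >= iso_start) & (outcomes == "fail")]
    if fail_after.size == 0:
        raise ValueError("no failed righting after anesthetic onset; cannot define LORR")
    lorr = float(fail_after[0] - iso_start)

    success_after = times[(times >= iso_stop) & (outcomes == "success")]
    if success_after.size == 0:
        raise ValueError("no successful righting after cessation; cannot define RORR")
    rorr = float(success_after[0] - iso_stop)
    return lorr, rorr


@dataclass
class AnimalSummary:
    """Per-animal condition summary (missing modalities leave fields None)."""

    animal_id: str
    group_label: str
    t_core_minus30: float | None = None  # °C at t = −30 min
    t_core_0: float | None = None  # °C at anesthetic onset
    t_core_32: float | None = None  # °C at cessation
    t_core_rorr: float | None = None  # °C at the RORR moment
    lorr_s: float | None = None
    rorr_s: float | None = None
    bsr_pct: float | None = None  # overall BSR, maintenance window
    band_power_maintenance: dict[str, float] = field(default_factory=dict)
    band_power_recovery: dict[str, float] = field(default_factory=dict)
    photometry_peak_z: float | None = None
    photometry_peak_time: float | None = None

    def metric(self, name: str) -> float | None:
        if name.startswith("rel_") and name.endswith("_maintenance"):
            return self.band_power_maintenance.get(name[4:-12])
        if name.startswith("rel_") and name.endswith("_recovery"):
            return self.band_power_recovery.get(name[4:-9])
        return getattr(self, name)


def summarize_animal(
    bundle,
    epoch_len: float = 60.0,
    detector_threshold: float | str = "adaptive",
) -> AnimalSummary:
    """Assemble one animal's summary from an ``AnimalBundle``-like object.

    The bundle needs ``animal_id``, ``condition`` and any of ``temperature``,
    ``eeg``, ``righting``, ``photometry``; missing modalities produce a
    partial summary with a logged note.
    """
    summary = AnimalSummary(
        animal_id=bundle.animal_id, group_label=bundle.condition.group_label
    )

    righting = getattr(bundle, "righting", None)
    iso_stop_s = MAINTENANCE_WINDOW[1] + 120.0  # default cessation marker
    eeg = getattr(bundle, "eeg", None)
    if eeg is not None and "iso_stop" in eeg.markers:
        iso_stop_s = eeg.markers["iso_stop"]
    if righting is not None:
        try:
            summary.lorr_s, summary.rorr_s = extract_lorr_rorr(righting, 0.0, iso_stop_s)
        except ValueError as err:
            logger.warning("%s: righting extraction failed: %s", bundle.animal_id, err)

    temp = getattr(bundle, "temperature", None)
    if temp is not None:
        summary.t_core_minus30 = temp.at(-30.0)
        summary.t_core_0 = temp.at(0.0)
        summary.t_core_32 = temp.at(32.0)
        if summary.rorr_s is not None:
            summary.t_core_rorr = temp.at((iso_stop_s + summary.rorr_s) / 60.0)
    else:
        logger.warning("%s: no temperature trace", bundle.animal_id)

    if eeg is not None:
        bp = compute_band_powers(eeg, epoch_len=epoch_len, window=MAINTENANCE_WINDOW)
        summary.band_power_maintenance = {b: bp.mean_relative(b) for b in BANDS}
        intervals = detect_suppressions(eeg, threshold_uv=detector_threshold)
        summary.bsr_pct = compute_bsr(intervals, eeg, window=MAINTENANCE_WINDOW).overall_pct
        if summary.rorr_s is not None and summary.rorr_s >= 2 * epoch_len:
            bp_rec = compute_band_powers(
                eeg,
                epoch_len=epoch_len,
                window=(iso_stop_s, iso_stop_s + summary.rorr_s),
            )
            summary.band_power_recovery = {b: bp_rec.mean_relative(b) for b in BANDS}
    else:
        logger.warning("%s: no EEG recording", bundle.animal_id)

    phot = getattr(bundle, "photometry", None)
    if phot is not None and "RORR" in phot.events:
        from .photometry import align_peri_event, compute_zscore, peak_stats

        stop = phot.events.get("iso_stop", 0.0)
        try:
            z = compute_zscore(phot, (stop - 50.0, stop))
            tensor = align_peri_event(
                z, [phot.events["RORR"]], pre=50.0, post=60.0, event_label="RORR"
            )
            pk = peak_stats(tensor, (-50.0, 60.0))[0]
            summary.photometry_peak_z = pk.peak_z
            summary.photometry_peak_time = pk.peak_time
        except ValueError as err:
            logger.warning("%s: photometry summary failed: %s", bundle.animal_id, err)
    return summary


@dataclass
class GroupComparison:
    groups: tuple[str, str]
    metric: str
    means: tuple[float, float]
    sems: tuple[float, float]
    n: tuple[int, int]
    test: str  # "paired t" | "unpaired t"
    statistic: float
    df: float
    p_value: float
    p_bonferroni: float


def compare_groups(
    summaries: list[AnimalSummary],
    metric: str,
    paired: bool = False,
    family_size: int = 1,
) -> GroupComparison:
    """Two-group comparison of one summary metric.

    Unpaired mode uses the pooled-variance two-sample t-test; paired mode
    requires equal n with animals matched by within-group order.  The
    Bonferroni-adjusted p multiplies by ``family_size`` (capped at 1).  Two
    groups with zero variance and equal means return p = 1 by convention.
    """
    groups: dict[str, list[float]] = {}
    for s in summaries:
        v = s.metric(metric)
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            groups.setdefault(s.group_label, []).append(float(v))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {sorted(groups)}")
    (ga, xa), (gb, xb) = groups.items()
    a, b = np.asarray(xa), np.asarray(xb)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two animals")

    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        res = stats.ttest_rel(a, b)
        test, df = "paired t", float(a.size - 1)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        test, df = "unpaired t", float(a.size + b.size - 2)
    t_stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t_stat):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf, 0.0
    return GroupComparison(
        groups=(ga, gb),
        metric=metric,
        means=(float(a.mean()), float(b.mean())),
        sems=(float(a.std(ddof=1) / math.sqrt(a.size)), float(b.std(ddof=1) / math.sqrt(b.size))),
        n=(int(a.size), int(b.size)),
        test=test,
        statistic=t_stat,
        df=df,
        p_value=p,
        p_bonferroni=min(1.0, p * family_size),
    )
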