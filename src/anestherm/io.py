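"""File formats, configuration and the end-to-end pipeline.

Conventions: CSV is comma-separated UTF-8 with ``.`` decimals; every column
name carries its unit (``time_s``, ``temp_c``, ``uv``, …); time is in seconds
internally and minutes only where the logging cadence makes minutes natural
(temperature logs).  EEG is read from CSV (``time_s,uv``) or continuous
EDF(+) (channel selected by label); synthetic cohorts are written as a
directory tree of plain-text files so they remain diffable and portable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import RightingEvents, compare_groups, summarize_animal
from .eeg import EEGRecording
from .errors import ConfigError
from .photometry import PhotometryTrace
from .regression import fit_breakpoint, fit_linear, fit_one_phase_decay
from .synthetic import (
    AnimalBundle,
    CohortConfig,
    Condition,
    SyntheticCohort,
    TemperatureTrace,
    generate_cohort,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# EEG readers
# ---------------------------------------------------------------------------


def read_eeg(
    path: str | Path,
    format: str | None = None,
    channel: str | None = None,
    t0: float = 0.0,
    markers: dict[str, float] | None = None,
) -> EEGRecording:
    """Read an EEG recording from CSV (``time_s,uv``) or EDF.

    CSV timing must be uniform to 1e-6 relative tolerance; the first offending
    gap is named in the error.  For EDF the rate comes from the header and the
    channel is selected by label (all available labels are listed on a
    mismatch).
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    markers = markers or {}
    if fmt == "csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns or "uv" not in df.columns:
            raise ValueError(f"{path}: expected columns time_s,uv; found {list(df.columns)}")
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError(f"{path}: need at least two samples")
        dt = np.diff(t)
        ref = dt[0]
        bad = np.flatnonzero(np.abs(dt - ref) > 1e-6 * max(abs(ref), 1e-12))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-uniform sampling at row {i + 1} "
                f"(gap {dt[i]:.9g} s vs expected {ref:.9g} s)"
            )
        return EEGRecording(
            samples=df["uv"].to_numpy(float), rate=1.0 / ref, t0=float(t[0]), markers=markers
        )
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        labels = raw.ch_names
        if channel is None:
            channel = labels[0]
        if channel not in labels:
            raise ValueError(f"{path}: channel {channel!r} not found; available: {labels}")
        data = raw.get_data(picks=[channel])[0] * 1e6  # MNE uses volts
        return EEGRecording(samples=data, rate=float(raw.info["sfreq"]), t0=t0, markers=markers)
    raise ValueError(f"unknown EEG format {fmt!r}")


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.times, "uv": rec.samples}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Other modality readers/writers
# ---------------------------------------------------------------------------


def write_temperature_csv(trace: TemperatureTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.times, "temp_c": trace.values}).to_csv(path, index=False)


def read_temperature_csv(path: str | Path, condition: Condition | None = None) -> TemperatureTrace:
    df = pd.read_csv(path)
    return TemperatureTrace(
        times=df["time_min"].to_numpy(float),
        values=df["temp_c"].to_numpy(float),
        condition=condition,
    )


def write_photometry_csv(trace: PhotometryTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "f_raw": trace.f_raw}).to_csv(path, index=False)


def read_photometry_csv(path: str | Path, events: dict[str, float] | None = None) -> PhotometryTrace:
    df = pd.read_csv(path)
    return PhotometryTrace(
        times=df["time_s"].to_numpy(float),
        f_raw=df["f_raw"].to_numpy(float),
        events=events or {},
    )


def write_righting_csv(log: RightingEvents, path: str | Path) -> None:
    pd.DataFrame({"time_s": log.times, "outcome": log.outcomes}).to_csv(path, index=False)


def read_righting_csv(path: str | Path) -> RightingEvents:
    df = pd.read_csv(path)
    return RightingEvents(
        times=df["time_s"].to_numpy(float), outcomes=df["outcome"].to_numpy(object)
    )


def read_events_csv(path: str | Path) -> dict[str, float]:
    """Event file: columns ``label,time_s``."""
    df = pd.read_csv(path)
    return {str(r["label"]): float(r["time_s"]) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# Cohort directory tree
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort as ``cohort.yaml`` plus one directory per animal with
    ``temp.csv``, ``eeg.csv``, ``photometry.csv``, ``righting.csv`` and
    ``truth.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    for a in cohort.animals:
        adir = out / a.animal_id
        adir.mkdir(exist_ok=True)
        write_temperature_csv(a.temperature, adir / "temp.csv")
        write_eeg_csv(a.eeg, adir / "eeg.csv")
        write_photometry_csv(a.photometry, adir / "photometry.csv")
        write_righting_csv(a.righting, adir / "righting.csv")
        pd.DataFrame(
            {"key": list(a.truth.keys()), "value": list(a.truth.values())}
        ).to_csv(adir / "truth.csv", index=False)
    return out


def _config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["conditions"] = [Condition(**c) for c in d.get("conditions", [])]
    profiles = {}
    for key, prof in (d.get("band_weight_profiles") or {}).items():
        ta, iso = (float(v) for v in str(key).split(","))
        profiles[(ta, iso)] = dict(prof)
    d["band_weight_profiles"] = profiles
    if d.get("phot_event_offsets", ...) is None:
        d.pop("phot_event_offsets")
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**d)


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Read a cohort tree back into memory (the per-sample EEG gate is
    ground-truth metadata and is not stored on disk; ``gate`` is None)."""
    root = Path(in_dir)
    with open(root / "cohort.yaml") as fh:
        config = _config_from_dict(yaml.safe_load(fh))
    by_label = {c.group_label: c for c in config.conditions}
    iso_stop_s = config.iso_stop_min * 60.0
    animals = []
    for adir in sorted(p for p in root.iterdir() if p.is_dir()):
        label = adir.name.rsplit("_", 1)[0]
        cond = by_label.get(label)
        if cond is None:
            logger.warning("skipping %s: no matching condition %r", adir, label)
            continue
        truth_df = pd.read_csv(adir / "truth.csv")
        truth = dict(zip(truth_df["key"], truth_df["value"].astype(float)))
        eeg = read_eeg(
            adir / "eeg.csv", markers={"iso_start": 0.0, "iso_stop": iso_stop_s}
        )
        events = {
            "iso_start": 0.0,
            "iso_stop": iso_stop_s,
            "LORR": truth.get("lorr_true_s", 0.0),
            "RORR": iso_stop_s + truth.get("rorr_true_s", 0.0),
        }
        animals.append(
            AnimalBundle(
                animal_id=adir.name,
                condition=cond,
                temperature=read_temperature_csv(adir / "temp.csv", cond),
                eeg=eeg,
                gate=None,
                photometry=read_photometry_csv(adir / "photometry.csv", events),
                righting=read_righting_csv(adir / "righting.csv"),
                truth=truth,
            )
        )
    return SyntheticCohort(config=config, animals=animals)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end run."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    epoch_len: float = 60.0  # s, band-power epoch
    detector_threshold: float | str = "adaptive"
    detector_min_dur: float = 0.5  # s
    comparison_metrics: tuple[str, ...] = ("rorr_s", "bsr_pct", "t_core_32")
    seed: int | None = None  # overrides cohort.seed when set
    log_level: str = "INFO"

    def validate(self) -> None:
        self.cohort.validate()
        if self.epoch_len < 4.0:
            raise ConfigError("epoch_len must be >= 4 s")
        if self.detector_min_dur <= 0:
            raise ConfigError("detector_min_dur must be positive")
        if isinstance(self.detector_threshold, str) and self.detector_threshold != "adaptive":
            raise ConfigError("detector_threshold must be a positive number or 'adaptive'")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = _config_from_dict(raw.pop("cohort", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"cohort"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    if "comparison_metrics" in raw:
        raw["comparison_metrics"] = tuple(raw["comparison_metrics"])
    cfg = PipelineConfig(cohort=cohort, **raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """simulate -> analyse -> fit -> compare; writes a deterministic JSON
    report plus CSVs, and a separate machine-readable stage-timing log.

    Returns the report dictionary.  Any stage failure aborts with the stage
    name in the exception message.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.seed is not None:
        config.cohort.seed = config.seed
    timings: dict[str, float] = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        timings[name] = time.perf_counter() - t0
        return result

    cohort = _stage("simulate", generate_cohort, config.cohort)
    _stage("write_cohort", write_cohort, cohort, out / "cohort")

    summaries = _stage(
        "summarize",
        lambda: [
            summarize_animal(
                a, epoch_len=config.epoch_len, detector_threshold=config.detector_threshold
            )
            for a in cohort.animals
        ],
    )
    sum_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    for band in ("delta", "theta", "alpha", "beta", "gamma"):
        sum_df[f"rel_{band}_maintenance"] = [
            s.band_power_maintenance.get(band) for s in summaries
        ]
    sum_df = sum_df.drop(columns=["band_power_maintenance", "band_power_recovery"])
    sum_df.to_csv(out / "summaries.csv", index=False)

    # regression fits across animals
    fits: dict[str, dict] = {}
    ta = np.array([a.condition.ambient_temp for a in cohort.animals], float)
    t32 = np.array([s.t_core_32 for s in summaries], float)
    rorr = np.array([s.rorr_s for s in summaries], float)
    ok = np.isfinite(t32) & np.isfinite(rorr)
    if np.ptp(ta[ok]) > 0 and ok.sum() >= 3:
        lf = _stage("fit_linear", fit_linear, ta[ok], t32[ok])
        fits["ambient_vs_core_linear"] = dataclasses.asdict(lf)
    if ok.sum() >= 4 and np.ptp(t32[ok]) > 0:
        df_fit = _stage("fit_decay", fit_one_phase_decay, t32[ok], rorr[ok])
        fits["rorr_vs_core_decay"] = dataclasses.asdict(df_fit)
    if ok.sum() >= 5 and np.ptp(t32[ok]) > 0:
        bp = _stage("fit_breakpoint", fit_breakpoint, t32[ok], rorr[ok])
        fits["rorr_vs_core_breakpoint"] = dataclasses.asdict(bp)

    # two-group comparisons where exactly two groups exist
    comparisons = []
    labels = sorted({s.group_label for s in summaries})
    if len(labels) == 2:
        for metric in config.comparison_metrics:
            try:
                c = compare_groups(summaries, metric, family_size=len(config.comparison_metrics))
                comparisons.append(dataclasses.asdict(c))
            except ValueError as err:
                logger.warning("comparison for %s skipped: %s", metric, err)
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)

    report = {
        "tool": "anestherm",
        "version": __version__,
        "seed": config.cohort.seed,
        "config": config.cohort.to_dict(),
        "n_animals": len(cohort.animals),
        "groups": labels,
        "fits": fits,
        "comparisons": comparisons,
    }
    report_json = json.dumps(report, indent=2, sort_keys=True, default=float)
    (out / "report.json").write_text(report_json)
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "seed": config.cohort.seed,
                "stage_timings_s": timings,
                "report_sha256": hashlib.sha256(report_json.encode()).hexdigest(),
            },
            indent=2,
        )
    )
    return report
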