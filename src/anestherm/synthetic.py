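"""Synthetic cohort generator.

Produces per-animal bundles — core-temperature trace, burst-suppression EEG,
fiber-photometry trace, righting-reflex flip log — with the statistical
structure the downstream analyses assume, plus ground-truth labels (the
per-sample suppression gate, the true LORR/RORR latencies, the equilibrium
temperatures) so every analysis stage can be tested against a known answer.

Generative model
----------------
* Core temperature follows first-order relaxation toward a condition-dependent
  equilibrium, ``dT/dt = -r (T - T_eq)``, stepped exactly at the 2-minute
  logging cadence with Gaussian measurement noise.  The equilibrium for the
  twelve packaged (ambient temperature × isoflurane dose) conditions is
  anchored to the reported endpoint temperature changes at anesthetic
  cessation; unlisted anesthetised conditions fall back to a linear map of
  ambient temperature.
* Emergence latency (RORR) follows a one-phase exponential decay in core
  temperature at cessation, ``latency = A exp(-k T) + C`` plus Gaussian noise,
  truncated at a positive floor.  The packaged per-condition cessation
  temperatures for the latency model are obtained by inverting this curve at
  the reported group-mean latencies, and the per-condition noise SD comes from
  the reported group SEMs.  (The reported endpoint temperature shifts and the
  reported latency means are not jointly consistent with the reported decay
  curve, so each synthetic output is anchored to its own summary statistic;
  see docs/methods.md.)
* EEG is a sum of five band-limited Gaussian noise components (δ/θ/α/β/γ)
  with condition-specific variance weights, multiplied by an alternating
  burst/suppression renewal gate.  The instantaneous suppression fraction is a
  logistic function of core temperature (bounded in [0, 1], approximately
  linear mid-range); suppressed samples are attenuated by a small factor.
* Photometry is a constant baseline plus slow sinusoidal drift, double-
  exponential calcium transients time-locked to LORR/RORR, and Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from ._rng import derive_seed
from .cohort import RightingEvents
from .eeg import BANDS, EEGRecording
from .errors import ConfigError
from .photometry import PhotometryTrace

# ---------------------------------------------------------------------------
# Packaged condition calibration table
# ---------------------------------------------------------------------------
# Keyed by (ambient_temp °C, isoflurane % v/v).  Per condition:
#   dT32      — group-mean core-temperature change (°C) at anesthetic
#               cessation (t = 32 min) relative to baseline, ± SEM (n = 7).
#   rorr      — group-mean RORR latency (s) ± SEM (n = 7).
#   delta     — group-mean δ-band relative power (fraction of 1–60 Hz total)
#               during maintenance.  Only the 0.8 % column was reported;
#               the remaining cells are plausible values chosen once
#               (δ share grows with dose and falls with ambient temperature).
CONDITION_TABLE: dict[tuple[float, float], dict[str, float]] = {
    (20.0, 0.8): {"dT32": -3.24, "dT32_sem": 0.58, "rorr": 348.57, "rorr_sem": 107.46, "delta": 0.5666},
    (20.0, 1.1): {"dT32": -3.54, "dT32_sem": 0.69, "rorr": 568.57, "rorr_sem": 159.21, "delta": 0.62},
    (20.0, 1.4): {"dT32": -4.51, "dT32_sem": 0.93, "rorr": 1074.29, "rorr_sem": 227.44, "delta": 0.66},
    (25.0, 0.8): {"dT32": -1.36, "dT32_sem": 0.21, "rorr": 99.71, "rorr_sem": 25.45, "delta": 0.3316},
    (25.0, 1.1): {"dT32": -2.08, "dT32_sem": 0.15, "rorr": 140.14, "rorr_sem": 16.36, "delta": 0.40},
    (25.0, 1.4): {"dT32": -2.22, "dT32_sem": 0.23, "rorr": 171.57, "rorr_sem": 27.08, "delta": 0.46},
    (32.0, 0.8): {"dT32": -0.27, "dT32_sem": 0.19, "rorr": 39.43, "rorr_sem": 16.21, "delta": 0.2781},
    (32.0, 1.1): {"dT32": -0.38, "dT32_sem": 0.12, "rorr": 46.00, "rorr_sem": 8.62, "delta": 0.33},
    (32.0, 1.4): {"dT32": -1.11, "dT32_sem": 0.36, "rorr": 45.71, "rorr_sem": 18.47, "delta": 0.38},
    (36.0, 0.8): {"dT32": 1.70, "dT32_sem": 0.20, "rorr": 9.43, "rorr_sem": 2.88, "delta": 0.25},
    (36.0, 1.1): {"dT32": 0.44, "dT32_sem": 0.38, "rorr": 10.57, "rorr_sem": 4.61, "delta": 0.30},
    (36.0, 1.4): {"dT32": 0.84, "dT32_sem": 0.18, "rorr": 9.71, "rorr_sem": 3.64, "delta": 0.34},
}

#: Fixed split of the non-δ share across the remaining bands.
_REST_SPLIT = {"theta": 0.35, "alpha": 0.15, "beta": 0.30, "gamma": 0.20}


def band_profile(delta_fraction: float) -> dict[str, float]:
    """Band-weight profile with the given δ share; the rest is split in
    fixed θ/α/β/γ proportions.  Weights sum to 1."""
    if not 0 <= delta_fraction < 1:
        raise ConfigError("delta fraction must be in [0, 1)")
    rest = 1.0 - delta_fraction
    prof = {"delta": delta_fraction}
    prof.update({b: rest * s for b, s in _REST_SPLIT.items()})
    return prof


def decay_curve(temp: np.ndarray | float, amp: float, rate: float, plateau: float):
    """One-phase decay ``latency = A·exp(-k·T) + C``."""
    return amp * np.exp(-rate * np.asarray(temp, dtype=float)) + plateau


def invert_decay(latency: float, amp: float, rate: float, plateau: float) -> float:
    """Temperature at which the one-phase decay equals ``latency``."""
    if latency <= plateau:
        raise ValueError("latency must exceed the plateau for inversion")
    return -math.log((latency - plateau) / amp) / rate


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Condition:
    """One experimental arm: chamber temperature, dose, optional perturbation.

    ``intervention`` models chemogenetic/optogenetic manipulation purely as a
    shift of the temperature equilibrium during [onset, offset] minutes:
    ``activate`` raises it by the configured delta, ``inhibit`` lowers it.
    """

    ambient_temp: float  # °C
    iso_conc: float  # % v/v; 0 = awake control
    group_label: str = ""
    intervention: str = "none"  # none | activate | inhibit
    intervention_onset: float | None = None  # min
    intervention_offset: float | None = None  # min

    def __post_init__(self) -> None:
        if not 15.0 <= self.ambient_temp <= 40.0:
            raise ConfigError(f"ambient_temp {self.ambient_temp} outside [15, 40] °C")
        if not 0.0 <= self.iso_conc <= 3.0:
            raise ConfigError(f"iso_conc {self.iso_conc} outside [0, 3] %")
        if self.intervention not in ("none", "activate", "inhibit"):
            raise ConfigError(f"unknown intervention {self.intervention!r}")
        if self.intervention != "none":
            if self.intervention_onset is None or self.intervention_offset is None:
                raise ConfigError("intervention requires onset and offset times")
            if not self.intervention_onset < self.intervention_offset:
                raise ConfigError("intervention onset must precede offset")
        if not self.group_label:
            self.group_label = f"Ta{self.ambient_temp:g}_iso{self.iso_conc:g}"

    @property
    def key(self) -> tuple[float, float]:
        return (float(self.ambient_temp), float(self.iso_conc))


@dataclass
class CohortConfig:
    """Full parameterisation of the generator.

    Defaults reproduce the packaged study conditions: isoflurane from t = 0 to
    t = 32 min, core temperature logged every 2 min, cage flipped every 15 s,
    n = 7 animals per group.
    """

    conditions: list[Condition] = field(
        default_factory=lambda: [Condition(20.0, 1.4), Condition(25.0, 1.4)]
    )
    n_per_group: int = 7
    seed: int = 0

    # temperature dynamics
    baseline_core_temp_mean: float = 36.9  # °C
    baseline_core_temp_sd: float = 0.25  # °C across animals
    temp_noise_sd: float = 0.15  # °C measurement noise per sample
    relaxation_rate: float = 0.15  # 1/min
    equilibrium_slope: float = 0.66  # °C/°C, fallback T_a -> equilibrium map
    equilibrium_offset: float = 14.79  # °C, fallback map intercept
    intervention_delta: float = 1.5  # °C equilibrium shift for "activate"
    temp_dt_min: float = 2.0  # logging cadence
    pre_min: float = 30.0  # baseline recording before anesthetic onset
    iso_stop_min: float = 32.0  # anesthetic cessation
    post_margin_min: float = 3.0  # recording continues past RORR

    # righting latencies
    rorr_amp: float = 20.3e5  # s (A)
    rorr_rate: float = 0.27  # 1/°C (k)
    rorr_plateau: float = -69.06  # s (C)
    rorr_noise_sd: float | None = None  # s; None -> per-condition SEM·√7
    rorr_floor: float = 1.0  # s, truncation floor
    lorr_mean: float = 90.0  # s; induction latency, temperature-independent
    lorr_sd: float = 20.0  # s
    flip_interval: float = 15.0  # s, righting-test cadence

    # EEG
    eeg_rate: float = 500.0  # Hz
    eeg_amplitude_uv: float = 50.0  # overall RMS scale, μV
    band_weight_profiles: dict[tuple[float, float], dict[str, float]] = field(
        default_factory=dict
    )
    suppression_t_half: float = 31.9  # °C, logistic midpoint
    suppression_steepness: float = 0.18  # 1/°C
    suppression_max: float = 0.9  # peak suppression fraction
    supp_mean_dur: float = 1.0  # s, mean suppression segment
    min_segment: float = 0.5  # s, minimum burst/suppression segment
    suppression_attenuation: float = 0.05  # amplitude factor during suppression

    # photometry
    phot_rate: float = 50.0  # Hz
    phot_baseline: float = 100.0  # raw fluorescence units
    phot_rise_tau: float = 0.5  # s
    phot_decay_tau: float = 3.0  # s
    phot_amplitude: float = 30.0  # transient peak, raw units
    phot_drift_amp: float = 2.0  # raw units
    phot_drift_period: float = 600.0  # s
    phot_noise_sd: float = 2.0  # raw units
    phot_margin_s: float = 120.0  # padding before first / after last event
    phot_event_offsets: dict[str, float] = field(
        default_factory=lambda: {"LORR": 0.0, "RORR": 0.0}
    )

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        labels = [c.group_label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate group labels in conditions")
        if self.relaxation_rate <= 0:
            raise ConfigError("relaxation_rate must be positive")
        if self.rorr_rate < 0 or self.rorr_amp <= 0:
            raise ConfigError("decay amplitude must be positive and rate non-negative")
        if self.eeg_rate < 200.0:
            raise ConfigError("eeg_rate must be >= 200 Hz (γ band below Nyquist)")
        if not 0.0 <= self.suppression_max <= 1.0:
            raise ConfigError("suppression_max must be in [0, 1]")
        if not 0.0 < self.suppression_attenuation < 1.0:
            raise ConfigError("suppression_attenuation must be in (0, 1)")
        if self.supp_mean_dur <= 0 or self.min_segment <= 0:
            raise ConfigError("segment durations must be positive")
        if self.phot_rise_tau <= 0 or self.phot_decay_tau <= 0:
            raise ConfigError("photometry time constants must be positive")
        if self.phot_rise_tau == self.phot_decay_tau:
            raise ConfigError("photometry rise and decay constants must differ")
        for prof in self.band_weight_profiles.values():
            if any(w < 0 for w in prof.values()):
                raise ConfigError("band weights must be non-negative")

    def profile_for(self, cond: Condition) -> dict[str, float]:
        """Band-weight profile for a condition: explicit override, then the
        packaged table's δ share, then a generic anesthesia profile."""
        if cond.key in self.band_weight_profiles:
            return self.band_weight_profiles[cond.key]
        if cond.key in CONDITION_TABLE:
            return band_profile(CONDITION_TABLE[cond.key]["delta"])
        if cond.iso_conc == 0:
            return band_profile(0.20)  # awake: broadband, modest δ
        return band_profile(0.45)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        d["band_weight_profiles"] = {
            f"{k[0]:g},{k[1]:g}": v for k, v in self.band_weight_profiles.items()
        }
        return d


@dataclass
class TemperatureTrace:
    """Core temperature (°C) sampled on a 2-min cadence; times in minutes
    relative to anesthetic onset (onset t = 0, cessation t = 32)."""

    times: np.ndarray  # min
    values: np.ndarray  # °C
    condition: Condition | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def at(self, t_min: float) -> float:
        """Temperature at the nearest logged sample (ties to the earlier one)."""
        d = np.abs(self.times - t_min)
        i = int(np.argmin(d))  # argmin returns the first (earlier) minimum
        return float(self.values[i])


@dataclass
class AnimalBundle:
    """All modalities for one synthetic animal, plus ground truth."""

    animal_id: str
    condition: Condition
    temperature: TemperatureTrace
    eeg: EEGRecording
    gate: np.ndarray  # bool, True = suppressed; same length as eeg.samples
    photometry: PhotometryTrace
    righting: RightingEvents
    truth: dict[str, float]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    animals: list[AnimalBundle]

    def by_group(self) -> dict[str, list[AnimalBundle]]:
        groups: dict[str, list[AnimalBundle]] = {}
        for a in self.animals:
            groups.setdefault(a.condition.group_label, []).append(a)
        return groups


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------


def anesthesia_equilibrium(config: CohortConfig, cond: Condition, baseline: float) -> float:
    """Equilibrium core temperature under anesthesia for this condition.

    Packaged conditions are anchored so the noise-free trajectory reaches the
    reported endpoint change exactly at cessation; unlisted anesthetised
    conditions use the linear ambient-temperature map; awake (dose 0) animals
    stay at their own baseline.
    """
    if cond.iso_conc == 0:
        return baseline
    if cond.key in CONDITION_TABLE:
        d32 = CONDITION_TABLE[cond.key]["dT32"]
        reach = 1.0 - math.exp(-config.relaxation_rate * config.iso_stop_min)
        return baseline + d32 / reach
    return config.equilibrium_slope * cond.ambient_temp + config.equilibrium_offset


def _equilibrium_at(
    config: CohortConfig, cond: Condition, baseline: float, t_min: float
) -> float:
    if t_min < 0 or t_min >= config.iso_stop_min:
        t_eq = baseline
    else:
        t_eq = anesthesia_equilibrium(config, cond, baseline)
    if (
        cond.intervention != "none"
        and cond.intervention_onset is not None
        and cond.intervention_onset <= t_min < cond.intervention_offset
    ):
        sign = 1.0 if cond.intervention == "activate" else -1.0
        t_eq += sign * config.intervention_delta
    return t_eq


def simulate_temperature_trace(
    config: CohortConfig,
    cond: Condition,
    seed: int,
    end_min: float | None = None,
) -> TemperatureTrace:
    """First-order relaxation of core temperature, stepped exactly per sample.

    Each 2-min step applies the exact solution of the linear ODE with the
    equilibrium held at its value at the step's start, so a noise-free trace
    with constant equilibrium equals the closed form
    ``T_eq + (T0 - T_eq)·exp(-r·t)`` to machine precision.
    """
    if config.relaxation_rate <= 0:
        raise ConfigError("relaxation_rate must be positive")
    rng = np.random.default_rng(seed)
    if end_min is None:
        end_min = config.iso_stop_min + config.post_margin_min
    dt = config.temp_dt_min
    times = np.arange(-config.pre_min, end_min + dt / 2, dt)
    baseline = config.baseline_core_temp_mean + rng.normal(0.0, config.baseline_core_temp_sd)
    decay = math.exp(-config.relaxation_rate * dt)

    state = baseline
    values = np.empty(times.size)
    values[0] = state
    for i in range(1, times.size):
        t_eq = _equilibrium_at(config, cond, baseline, times[i - 1])
        state = t_eq + (state - t_eq) * decay
        values[i] = state
    values = values + rng.normal(0.0, config.temp_noise_sd, size=values.size)
    return TemperatureTrace(times=times, values=np.clip(values, 20.0, 42.0), condition=cond)


# ---------------------------------------------------------------------------
# Righting latencies
# ---------------------------------------------------------------------------


def condition_rorr_params(config: CohortConfig, cond: Condition) -> tuple[float, float]:
    """(effective cessation temperature, latency noise SD) for a condition.

    Packaged conditions invert the decay curve at the reported group-mean
    latency, and use the reported SEM·√7 as the SD; unlisted conditions use
    the temperature model's equilibrium and a 15 % relative SD.
    """
    amp, rate, plateau = config.rorr_amp, config.rorr_rate, config.rorr_plateau
    if cond.key in CONDITION_TABLE:
        entry = CONDITION_TABLE[cond.key]
        t_star = invert_decay(entry["rorr"], amp, rate, plateau)
        sd = entry["rorr_sem"] * math.sqrt(7.0)
    else:
        t_star = anesthesia_equilibrium(config, cond, config.baseline_core_temp_mean)
        sd = 0.15 * max(float(decay_curve(t_star, amp, rate, plateau)), config.rorr_floor)
    if config.rorr_noise_sd is not None:
        sd = config.rorr_noise_sd
    return t_star, sd


def simulate_rorr_latency(
    config: CohortConfig,
    t_core_at_cessation: float,
    seed: int,
    noise_sd: float | None = None,
) -> float:
    """Draw one emergence latency at the given cessation core temperature."""
    rng = np.random.default_rng(seed)
    val = float(
        decay_curve(t_core_at_cessation, config.rorr_amp, config.rorr_rate, config.rorr_plateau)
    )
    sd = noise_sd if noise_sd is not None else (config.rorr_noise_sd or 0.0)
    if sd > 0:
        val += rng.normal(0.0, sd)
    return max(val, config.rorr_floor)


def simulate_condition_rorr(
    config: CohortConfig, cond: Condition, n: int, seed: int
) -> np.ndarray:
    """Draw n latencies for one condition at its calibrated cessation
    temperature and noise level."""
    t_star, sd = condition_rorr_params(config, cond)
    center = float(decay_curve(t_star, config.rorr_amp, config.rorr_rate, config.rorr_plateau))
    rng = np.random.default_rng(seed)
    vals = center + rng.normal(0.0, sd, size=n)
    return np.maximum(vals, config.rorr_floor)


def simulate_righting(
    config: CohortConfig, lorr_true: float, rorr_true: float
) -> RightingEvents:
    """Flip log at the configured cadence implied by the true latencies.

    The animal rights itself at every flip before induction-LORR and after
    cessation+RORR; in between, every flip fails.
    """
    iso_stop_s = config.iso_stop_min * 60.0
    dt = config.flip_interval
    t_end = iso_stop_s + rorr_true + 2 * dt
    times = np.arange(-2 * dt, t_end + dt / 2, dt)
    outcomes = np.where(
        (times >= lorr_true) & (times < iso_stop_s + rorr_true), "fail", "success"
    )
    return RightingEvents(times=times, outcomes=outcomes)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


def suppression_fraction(config: CohortConfig, temp: np.ndarray | float):
    """Logistic map from core temperature to target suppression fraction."""
    return config.suppression_max * expit(
        config.suppression_steepness * (config.suppression_t_half - np.asarray(temp, float))
    )


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit *in-band* power band-limited Gaussian noise.

    White noise is band-limited by zeroing spectral bins outside [lo, hi]
    (a brick-wall filter), so essentially no component energy falls into the
    inter-band gaps or another band, and the component is normalised by its
    measured power inside its nominal band under the same Welch convention
    the analysis uses.  Together these make the configured weights coincide
    with the reported relative band powers to well within 2 % absolute.
    """
    from scipy.signal import welch

    hi = min(hi, 0.45 * fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs_fft = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs_fft < lo) | (freqs_fft > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    nperseg = min(int(4 * fs), n)
    freqs, psd = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    mask = (freqs >= lo) & (freqs <= hi)
    p = np.trapezoid(psd[mask], freqs[mask])
    return x / math.sqrt(p) if p > 0 else x


def _shifted_exp(rng: np.random.Generator, mean: float, minimum: float) -> float:
    if mean <= minimum:
        return minimum
    return minimum + rng.exponential(mean - minimum)


def _render_gate(
    config: CohortConfig,
    times_s: np.ndarray,
    temp_trace: TemperatureTrace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternating burst/suppression renewal gate over the anesthesia window.

    Segment durations are shifted exponentials (minimum segment length
    enforced) whose means are set so the expected suppressed fraction equals
    the logistic map of the core temperature at each segment's start.  When
    the target fraction would demand a mean burst shorter than the minimum
    segment, the burst mean is pinned there and the suppression mean is
    lengthened instead, keeping the expected fraction exact.
    """
    gate = np.zeros(times_s.size, dtype=bool)
    iso_start_s, iso_stop_s = 0.0, config.iso_stop_min * 60.0
    t = max(iso_start_s, times_s[0])
    t_end = min(iso_stop_s, times_s[-1])
    fs = config.eeg_rate
    mu_s0, min_seg = config.supp_mean_dur, config.min_segment
    suppressed = False  # start each anesthetic period in a burst
    while t < t_end:
        temp_here = float(np.interp(t / 60.0, temp_trace.times, temp_trace.values))
        f = float(suppression_fraction(config, temp_here))
        if f <= 1e-9:
            break  # no suppression at this depth: burst to end of window
        if f >= 1.0 - 1e-9:
            gate[times_s >= t] = True
            break
        mu_b = mu_s0 * (1.0 - f) / f
        mu_s = mu_s0
        if mu_b < min_seg:
            mu_b = min_seg
            mu_s = min_seg * f / (1.0 - f)
        dur = _shifted_exp(rng, mu_s if suppressed else mu_b, min_seg)
        if suppressed:
            i0 = int(np.ceil((t - times_s[0]) * fs))
            i1 = int(np.ceil((t + dur - times_s[0]) * fs))
            gate[max(i0, 0) : max(i1, 0)] = True
        t += dur
        suppressed = not suppressed
    # clip gate to the anesthesia window
    gate &= (times_s >= iso_start_s) & (times_s < iso_stop_s)
    return gate


def simulate_eeg(
    config: CohortConfig,
    cond: Condition,
    temp_trace: TemperatureTrace,
    seed: int,
) -> tuple[EEGRecording, np.ndarray]:
    """Band-weighted noise EEG with a temperature-driven suppression gate.

    Returns the recording and the ground-truth per-sample gate
    (True = suppressed).  The record spans the temperature trace.
    """
    if config.eeg_rate < 200.0:
        raise ConfigError("eeg_rate must be >= 200 Hz (γ band below Nyquist)")
    rng = np.random.default_rng(seed)
    fs = config.eeg_rate
    t0_s = temp_trace.times[0] * 60.0
    n = int(round((temp_trace.times[-1] - temp_trace.times[0]) * 60.0 * fs))
    times_s = t0_s + np.arange(n) / fs

    profile = config.profile_for(cond)
    sig = np.zeros(n)
    for band, (lo, hi) in BANDS.items():
        w = profile.get(band, 0.0)
        if w < 0:
            raise ConfigError("band weights must be non-negative")
        if w > 0:
            sig += math.sqrt(w) * _band_noise(rng, n, lo, hi, fs)
    sd = sig.std()
    if sd > 0:
        sig *= config.eeg_amplitude_uv / sd

    if cond.iso_conc > 0 and config.suppression_max > 0:
        gate = _render_gate(config, times_s, temp_trace, rng)
    else:
        gate = np.zeros(n, dtype=bool)
    sig = np.where(gate, sig * config.suppression_attenuation, sig)

    rec = EEGRecording(
        samples=sig,
        rate=fs,
        t0=t0_s,
        markers={"iso_start": 0.0, "iso_stop": config.iso_stop_min * 60.0},
    )
    return rec, gate


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------


def kernel_peak_offset(rise_tau: float, decay_tau: float) -> float:
    """Time to peak of the double-exponential kernel
    ``exp(-t/τ_d) - exp(-t/τ_r)``."""
    if rise_tau <= 0 or decay_tau <= 0 or rise_tau == decay_tau:
        raise ConfigError("time constants must be positive and distinct")
    return (rise_tau * decay_tau / (decay_tau - rise_tau)) * math.log(decay_tau / rise_tau)


def _kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    tt = np.maximum(np.asarray(t, dtype=float), 0.0)  # avoid exp overflow for t<0
    k = np.where(t >= 0, np.exp(-tt / decay_tau) - np.exp(-tt / rise_tau), 0.0)
    t_pk = kernel_peak_offset(rise_tau, decay_tau)
    peak = math.exp(-t_pk / decay_tau) - math.exp(-t_pk / rise_tau)
    return k / peak


def simulate_photometry(
    config: CohortConfig, events: dict[str, float], seed: int
) -> PhotometryTrace:
    """Baseline + slow drift + event-locked calcium transients + noise.

    ``events`` maps labels (iso_start, iso_stop, LORR, RORR, …) to absolute
    times in seconds; transients are injected at the events named in
    ``config.phot_event_offsets`` (shifted by the configured offsets).
    """
    if not events:
        raise ValueError("events must be non-empty")
    if config.phot_rise_tau <= 0 or config.phot_decay_tau <= 0:
        raise ConfigError("photometry time constants must be positive")
    rng = np.random.default_rng(seed)
    fs = config.phot_rate
    t_lo = min(events.values()) - config.phot_margin_s
    t_hi = max(events.values()) + config.phot_margin_s
    n = int(round((t_hi - t_lo) * fs)) + 1
    times = t_lo + np.arange(n) / fs

    f = np.full(n, config.phot_baseline, dtype=float)
    if config.phot_drift_amp != 0:
        f += config.phot_drift_amp * np.sin(2 * np.pi * times / config.phot_drift_period)
    for label, offset in config.phot_event_offsets.items():
        if label in events:
            f += config.phot_amplitude * _kernel(
                times - (events[label] + offset), config.phot_rise_tau, config.phot_decay_tau
            )
    if config.phot_noise_sd > 0:
        f += rng.normal(0.0, config.phot_noise_sd, size=n)
    return PhotometryTrace(times=times, f_raw=f, events=dict(events))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort deterministically from the master seed.

    Per-animal substream seeds are derived by integer hashing of
    (master seed, condition index, animal index), so each animal's data is
    independent of generation order.
    """
    config.validate()
    animals: list[AnimalBundle] = []
    for ci, cond in enumerate(config.conditions):
        t_star, rorr_sd = condition_rorr_params(config, cond)
        for ai in range(config.n_per_group):
            base = derive_seed(config.seed, ci, ai)
            rng_l = np.random.default_rng(derive_seed(base, 1))
            lorr_true = max(
                float(rng_l.normal(config.lorr_mean, config.lorr_sd)),
                config.flip_interval,
            )
            rorr_true = simulate_rorr_latency(
                config, t_star, derive_seed(base, 2), noise_sd=rorr_sd
            )
            end_min = config.iso_stop_min + rorr_true / 60.0 + config.post_margin_min
            temp = simulate_temperature_trace(config, cond, derive_seed(base, 3), end_min=end_min)
            eeg_rec, gate = simulate_eeg(config, cond, temp, derive_seed(base, 4))
            righting = simulate_righting(config, lorr_true, rorr_true)
            iso_stop_s = config.iso_stop_min * 60.0
            phot = simulate_photometry(
                config,
                {
                    "iso_start": 0.0,
                    "iso_stop": iso_stop_s,
                    "LORR": lorr_true,
                    "RORR": iso_stop_s + rorr_true,
                },
                derive_seed(base, 5),
            )
            iso_mask = (eeg_rec.times >= 0.0) & (eeg_rec.times < iso_stop_s)
            truth = {
                "lorr_true_s": lorr_true,
                "rorr_true_s": rorr_true,
                "rorr_temp_c": t_star,
                "equilibrium_temp_c": anesthesia_equilibrium(
                    config, cond, config.baseline_core_temp_mean
                ),
                "gate_fraction": float(gate[iso_mask].mean()) if iso_mask.any() else 0.0,
            }
            animals.append(
                AnimalBundle(
                    animal_id=f"{cond.group_label}_{ai:02d}",
                    condition=cond,
                    temperature=temp,
                    eeg=eeg_rec,
                    gate=gate,
                    photometry=phot,
                    righting=righting,
                    truth=truth,
                )
            )
    return SyntheticCohort(config=config, animals=animals)
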