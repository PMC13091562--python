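# Methods

This note documents the models implemented in `anestherm`, the calibration of
the synthetic-data generator, the numerical choices made where the design was
genuinely open, and the limits of what the synthetic tests can establish
about real recordings.

## The scientific setting

Mice anesthetised with isoflurane lose thermoregulation; their core
temperature (T_core, logged every 2 min by an implanted probe) relaxes toward
a level set by the chamber's ambient temperature (T_a) and the anesthetic
dose. Anesthesia runs from t = 0 to t = 32 min. Depth of anesthesia is read
out from EEG — the burst-suppression ratio (BSR) and the δ-band share of
spectral power — and emergence is read out behaviourally as the latency from
isoflurane cessation to recovery of the righting reflex (RORR), probed by
flipping the cage every 15 s. Emergence latency falls steeply with rising
cessation T_core and flattens above an inflection near 31.9 °C; the analysis
models this with a one-phase exponential decay and a segmented (breakpoint)
regression.

## Analysis models

**Band powers.** Per-epoch (default 60 s) averaged modified periodogram:
4-s Hann segments, 50 % overlap (0.25 Hz resolution, adequate for the 1-Hz
lower band edge). Absolute power is the PSD integrated over the closed band
intervals δ 1–4, θ 5–8, α 9–12, β 13–25, γ 26–60 Hz; relative power divides
by total power in 1–60 Hz. The band edges deliberately leave gaps (4–5 Hz,
8–9 Hz, 12–13 Hz, 25–26 Hz), so the five relative powers sum to slightly
less than 1; this is fidelity to the band convention, not a bug. No line-
noise handling is applied by default (synthetic data has none); a notch is a
caller-side concern for real data.

**Suppression detection.** The detector is not specified by the analysis
convention we follow, so it is declared here: a sample is suppressed iff the
moving-RMS envelope (0.1-s window) stays below threshold for ≥ 0.5 s. The
default threshold is adaptive — 0.25 × the awake-baseline RMS (samples
before anesthetic onset) — which makes BSR invariant to amplitude rescaling;
an absolute μV threshold is accepted too. A first-order boundary correction
dilates detected runs by W·(1/2 − (threshold/RMS_burst)²), where W is the
envelope window: a centred moving-RMS crosses the threshold only once the
window is almost clear of burst signal, i.e. systematically *inside* the true
suppression epoch, and the correction places interval edges back on the
transitions. Runs are dilated and merged before the minimum-duration rule so
epochs just above the minimum are not lost. On synthetic cohorts the detected
mask agrees with the generator's ground-truth gate on ≈ 98–99 % of anesthesia
samples across depths.

**BSR.** Suppressed duration / analysed duration × 100, reported per 60-s
bin and overall (the overall value equals the duration-weighted bin mean).
Analysis windows: maintenance = 0–30 min; recovery = cessation (32 min) to
RORR.

**Photometry.** ΔF/F and Z use the mean (and SD) of a 50-s baseline window
immediately before the alignment event — anesthetic onset for LORR-aligned
analyses, cessation for RORR-aligned ones — so baseline samples have Z mean 0
and SD 1 by construction. The isosbestic (410 nm) control channel is read but
not regressed out: no correction formula is part of the convention we follow,
and motion correction is out of scope. Peri-event tensors align Z windows
(inclusive endpoints, event at offset 0); the peak-search window is a
required explicit parameter because the appropriate bound (e.g. the first
20 s after onset) depends on the question. Ties in the peak search break
toward the earliest time.

**Righting latencies.** LORR = first *failed* righting at/after onset;
RORR = first *successful* righting at/after cessation. A log with no
qualifying flip raises rather than silently truncating. The first-failure
rule is a declared choice (a sustained-failure variant would differ by at
most one 15-s flip in practice); latencies are resolved only to the flip
cadence.

**Regression.**
* Linear: OLS; R² = 1 − SSE/SST; slope p-value from the t distribution.
* One-phase decay `y = A·e^(−k·x) + C`: bounded (k ≥ 0) Levenberg–Marquardt
  via trust-region reflective, multi-started from five plateau candidates
  just below min(y), each seeding (A₀, k₀) by log-linear regression of
  log(y − C₀) on x; best SSE kept; a constant response returns the documented
  degenerate fit (A = 0, k = 0, C = ȳ); non-convergence of every start is
  flagged, never silently wrong. k ≥ 0 is enforced because emergence latency
  cannot increase with temperature in this model family. Spreadsheet
  parameterisations (Y0, plateau, K) map as A = Y0 − plateau, C = plateau,
  k = K.
* Breakpoint `y = b1·(x < b2)·(x − b2) + b3`: b2 profiled on a 0.01 °C grid
  over the interior of x (≥ 2 points on each side), conditional (b1, b3) in
  closed form, ties broken toward the smallest b2, then a bounded continuous
  polish within one grid step. Flat data are flagged unidentifiable with
  b3 = ȳ.
* Group comparisons: extra-sum-of-squares F tests on nested models —
  parallel lines, then elevation; shared vs. separate decay rate k with
  (1, n − 6) df. Unweighted least squares throughout. The shared-k joint fit
  can numerically edge out the separate fits, so F is clamped at 0.
* Per-metric group tests: pooled-variance unpaired t or paired t;
  Bonferroni-adjusted p = min(1, p × family size). Repeated-measures ANOVA
  is deliberately not provided; the per-band family of five two-sample tests
  with a Bonferroni factor is a documented simplification.

## Synthetic-data generator

The generator's defaults are the packaged study conditions: twelve
(T_a × dose) cells, n = 7 per group, onset t = 0, cessation t = 32 min,
2-min temperature cadence, 15-s flip cadence, 500 Hz EEG, 50 Hz photometry.

**Temperature.** First-order relaxation dT/dt = −r(T − T_eq), r = 0.15/min
(near-equilibrium by 30 min, matching the observed trace shape), stepped with
the exact per-interval solution of the linear ODE (equilibrium held constant
within each 2-min step), plus Gaussian measurement noise (SD 0.15 °C).
Noise-free traces therefore match the closed form to machine precision — the
basis of an oracle test. Baseline 36.9 ± 0.25 °C across animals. For the
twelve packaged conditions the anesthetic equilibrium is anchored so the
noise-free endpoint change at t = 32 equals the reported group mean (e.g.
−4.51 °C at 20 °C/1.4 %, +1.70 °C at 36 °C/0.8 %); unlisted anesthetised
conditions fall back to the linear ambient map T_eq = 0.66·T_a + 14.79.
Chemogenetic/optogenetic interventions are represented solely as a ±1.5 °C
(configurable) equilibrium shift during their window.

**Emergence latency.** latency = A·e^(−k·T*) + C + ε, with the packaged curve
(A = 2.03 × 10⁶ s, k = 0.27 /°C, C = −69.06 s), truncated at a 1-s floor.
T* is the condition's effective cessation temperature. **Calibration note:**
the reported endpoint temperature changes and the reported group-mean
latencies are not jointly consistent with the packaged decay curve (the
20 °C/1.4 % endpoint implies ≈ 254 s, far from the reported 1074 s group
mean). The generator therefore anchors each output to its own reported
summary: temperature traces to the endpoint changes, and latency draws to the
group-mean latencies via inversion of the decay curve (T* =
−ln((mean − C)/A)/k). Latency noise SD is the reported per-condition
SEM × √7. The floor truncation inflates the coldest condition's mean by
≈ 0.9 % — part of the model, since latencies cannot be negative. Induction
latency (LORR) is temperature-independent, N(90 s, 20 s) clipped below at one
flip interval, consistent with induction occurring before hypothermia
develops.

**EEG.** Sum of five Gaussian noise components, one per band, each
band-limited by zeroing spectral bins outside its band (brick-wall) and
normalised to unit power *within its nominal band under the same Welch
convention the analysis uses*, then weighted by the condition's profile and
scaled to 50 μV RMS overall. This makes configured weights coincide with
measured relative powers to well within 2 % absolute; the residual ≈ 1.5-point
deflation of a 57 % δ share is Hann-window smearing into the inter-band gaps,
an inherent property of the gapped band convention rather than of the
generator. δ shares for the three reported 0.8 % conditions are the reported
values (56.66 / 33.16 / 27.81 %); the nine unreported cells are plausible
values chosen once (δ rising with dose, falling with T_a), with the non-δ
remainder split θ:α:β:γ = 0.35:0.15:0.30:0.20.

Burst suppression is an alternating renewal gate over the anesthesia window:
suppression segments with mean 1.0 s, minimum segment 0.5 s (shifted
exponentials), burst means set so the expected suppressed fraction equals a
logistic map of instantaneous T_core — midpoint 31.9 °C, steepness 0.18 /°C,
maximum 0.9 (bounded in [0, 1] and approximately linear mid-range, slope
≈ −4 BSR %/°C, consistent with the observed linear BSR–T_core trend over the
physiological range). When the target fraction would demand burst segments
below the minimum, the burst mean is pinned at the minimum and the
suppression mean lengthened, keeping the expected fraction exact. Suppressed
samples are attenuated by 0.05 — far below any sane detector threshold. The
gate is returned as ground truth.

**Photometry.** Baseline 100 (arbitrary units) + slow sinusoidal drift
(amplitude 2, period 600 s) + double-exponential transients
(rise τ 0.5 s, decay τ 3 s, peak amplitude 30) at LORR and RORR + Gaussian
noise (SD 2). The kernel's peak offset has a closed form,
τ_r·τ_d/(τ_d − τ_r)·ln(τ_d/τ_r), used as an oracle.

**Reproducibility.** A master seed is expanded into per-animal, per-signal
substream seeds by splitmix64-style hashing of (seed, condition index, animal
index, stream index): identical configurations are byte-identical after
serialisation, and each animal is independent of generation order.

**What the generator does and does not emulate.** It reproduces the joint
*statistical* structure the analyses assume — temperature-dependent
suppression, dose- and ambient-dependent equilibria, decay-law latencies,
event-locked transients — with known ground truth. It does not emulate
artifacts, electrode drift, line noise, movement transients, isosbestic
crosstalk, pharmacokinetics, or circuit dynamics. Passing tests therefore
establish that the analysis code computes its statistics correctly and
recovers known generating parameters at realistic noise levels; they do not
validate robustness to real-world contamination.

## File formats and units

CSV, comma-separated UTF-8, column names carrying units (`time_s`, `uv`,
`time_min`, `temp_c`, `f_raw`); seconds internally, minutes only for the
2-min temperature logs. EEG can also be read from continuous EDF(+) via MNE
(channel by label; header rate); cohorts are written as plain-text directory
trees (`cohort.yaml` config echo plus per-animal CSVs including the
ground-truth summary). Every pipeline run writes a deterministic
`report.json` (tool version, config echo, fits, comparisons) and a separate
`run_log.json` with stage timings and the seed, so the report hash is
reproducible.

## Problem sizes

Tests and the acceptance script use deliberately scaled problem sizes chosen
to estimate each quantity well inside its tolerance: 30-minute single-channel
records at 250–500 Hz, cohorts of 2–7 animals per group for end-to-end runs,
200 replicates for power/recovery simulations, and 20 seeded realisations for
spectral averages. These are the package's own defaults for its examples; all
sizes are parameters.

## Known limitations

* The breakpoint model forces an exact plateau above b2; a shallow second
  slope would bias b2 slightly.
* The decay-rate comparison assumes homoscedastic residuals across groups.
* Adaptive suppression thresholding needs ≥ 1 s of pre-anesthetic baseline;
  records without one must supply an absolute threshold.
* EDF writing is not provided; synthetic cohorts are written as CSV.
* Bootstrap/profile confidence intervals for the nonlinear fits are future
  work.
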