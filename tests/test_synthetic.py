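"""Generator correctness: closed-form oracles, ground-truth gates, determinism."""

import numpy as np
import pytest

from anestherm import ConfigError
from anestherm.eeg import compute_band_powers, BANDS
from anestherm.synthetic import (
    CohortConfig,
    Condition,
    TemperatureTrace,
    anesthesia_equilibrium,
    band_profile,
    condition_rorr_params,
    decay_curve,
    generate_cohort,
    kernel_peak_offset,
    simulate_condition_rorr,
    simulate_eeg,
    simulate_photometry,
    simulate_rorr_latency,
    simulate_temperature_trace,
    suppression_fraction,
)


def noise_free_config(**kw) -> CohortConfig:
    return CohortConfig(baseline_core_temp_sd=0.0, temp_noise_sd=0.0, **kw)


class TestTemperature:
    def test_matches_closed_form_exponential(self):
        """Noise-free trajectory equals T_eq + (T0 - T_eq)e^{-rt} to 1e-6 °C."""
        cfg = noise_free_config()
        cond = Condition(20.0, 1.4)
        tr = simulate_temperature_trace(cfg, cond, seed=1)
        t_eq = anesthesia_equilibrium(cfg, cond, cfg.baseline_core_temp_mean)
        m = (tr.times >= 0) & (tr.times <= cfg.iso_stop_min)
        oracle = t_eq + (cfg.baseline_core_temp_mean - t_eq) * np.exp(
            -cfg.relaxation_rate * tr.times[m]
        )
        assert np.max(np.abs(tr.values[m] - oracle)) < 1e-6

    def test_vanishing_relaxation_gives_constant_trace(self):
        # an uncalibrated condition, so the equilibrium is the plain linear
        # ambient map and a vanishing rate freezes the trace at baseline
        cfg = noise_free_config(relaxation_rate=1e-12)
        tr = simulate_temperature_trace(cfg, Condition(22.0, 1.4), seed=1)
        assert np.allclose(tr.values, cfg.baseline_core_temp_mean, atol=1e-6)

    def test_warm_chamber_raises_endpoint_temperature(self):
        """The 36 °C / 0.8 % condition is configured for a +1.70 °C endpoint."""
        cfg = noise_free_config()
        tr = simulate_temperature_trace(cfg, Condition(36.0, 0.8), seed=3)
        d32 = tr.at(32.0) - cfg.baseline_core_temp_mean
        assert d32 == pytest.approx(1.70, abs=1e-9)
        assert tr.at(32.0) > tr.at(0.0)

    def test_baseline_segment_fluctuates_about_baseline_mean(self):
        cfg = CohortConfig(baseline_core_temp_sd=0.0, temp_noise_sd=0.1)
        tr = simulate_temperature_trace(cfg, Condition(20.0, 1.4), seed=5)
        pre = tr.values[tr.times < 0]
        assert abs(pre.mean() - cfg.baseline_core_temp_mean) < 0.15

    def test_intervention_shifts_equilibrium(self):
        cfg = noise_free_config(intervention_delta=2.0)
        cond = Condition(
            25.0, 1.4, intervention="activate",
            intervention_onset=0.0, intervention_offset=32.0,
        )
        plain = Condition(25.0, 1.4, group_label="plain")
        tr_a = simulate_temperature_trace(cfg, cond, seed=1)
        tr_p = simulate_temperature_trace(cfg, plain, seed=1)
        assert tr_a.at(32.0) > tr_p.at(32.0)

    def test_non_positive_relaxation_rate_rejected(self):
        cfg = CohortConfig()
        cfg.relaxation_rate = 0.0
        with pytest.raises(ConfigError):
            simulate_temperature_trace(cfg, Condition(25.0, 0.8), seed=0)


class TestRorrLatency:
    def test_noise_free_value_is_the_decay_curve(self):
        cfg = CohortConfig()
        val = simulate_rorr_latency(cfg, 31.88, seed=0, noise_sd=0.0)
        expected = decay_curve(31.88, cfg.rorr_amp, cfg.rorr_rate, cfg.rorr_plateau)
        assert val == pytest.approx(float(expected), rel=1e-12)

    def test_zero_rate_gives_constant_latency(self):
        cfg = CohortConfig(rorr_rate=0.0)
        vals = [simulate_rorr_latency(cfg, t, seed=0, noise_sd=0.0) for t in (25.0, 30.0, 35.0)]
        assert vals[0] == vals[1] == vals[2] == pytest.approx(cfg.rorr_amp + cfg.rorr_plateau)

    def test_latency_strictly_decreasing_in_temperature(self):
        cfg = CohortConfig()
        temps = np.linspace(24.0, 38.0, 30)
        vals = np.array([simulate_rorr_latency(cfg, t, seed=0, noise_sd=0.0) for t in temps])
        free = vals > cfg.rorr_floor  # below the floor the truncation flattens
        assert np.all(np.diff(vals[free]) < 0)

    def test_cohort_mean_converges_to_curve_value(self):
        """Grand mean over 200 cohorts of n = 7 approaches the curve value at
        the condition's calibrated cessation temperature."""
        cfg = CohortConfig()
        cond = Condition(25.0, 1.4)
        t_star, sd = condition_rorr_params(cfg, cond)
        center = float(decay_curve(t_star, cfg.rorr_amp, cfg.rorr_rate, cfg.rorr_plateau))
        means = [simulate_condition_rorr(cfg, cond, 7, seed=500 + i).mean() for i in range(200)]
        se = sd / np.sqrt(200 * 7)
        assert abs(np.mean(means) - center) < 3.5 * se


class TestEEGGenerator:
    @staticmethod
    def _const_trace(cond, temp, start=-6.0, end=32.0):
        t = np.arange(start, end + 0.1, 2.0)
        return TemperatureTrace(times=t, values=np.full(t.size, temp), condition=cond)

    def test_zero_suppression_gives_all_burst_gate(self):
        cfg = CohortConfig(eeg_rate=250.0, suppression_max=0.0)
        cond = Condition(20.0, 1.4)
        _, gate = simulate_eeg(cfg, cond, self._const_trace(cond, 30.0), seed=1)
        assert not gate.any()

    def test_realized_gate_fraction_matches_logistic_target(self):
        """Over a 32-min record the renewal gate realizes the configured
        suppression fraction within 3 binomial-style SEs."""
        from scipy.special import logit

        cfg = CohortConfig(eeg_rate=250.0)
        cond = Condition(20.0, 1.4)
        f = 0.35
        temp = cfg.suppression_t_half - logit(f / cfg.suppression_max) / cfg.suppression_steepness
        rec, gate = simulate_eeg(cfg, cond, self._const_trace(cond, temp), seed=7)
        iso = (rec.times >= 0) & (rec.times < cfg.iso_stop_min * 60)
        realized = gate[iso].mean()
        mu_b = cfg.supp_mean_dur * (1 - f) / f
        n_seg = cfg.iso_stop_min * 60 / (cfg.supp_mean_dur + mu_b)
        se = np.sqrt(f * (1 - f) / n_seg)
        assert abs(realized - f) < 3 * se

    def test_delta_dominant_profile_yields_delta_dominant_power(self):
        cfg = CohortConfig(
            eeg_rate=250.0,
            suppression_max=0.0,
            band_weight_profiles={(25.0, 0.8): band_profile(0.7)},
        )
        cond = Condition(25.0, 0.8)
        rec, _ = simulate_eeg(cfg, cond, self._const_trace(cond, 34.0, start=0.0, end=10.0), seed=2)
        bp = compute_band_powers(rec, epoch_len=60.0)
        delta = bp.mean_relative("delta")
        assert all(delta > bp.mean_relative(b) for b in BANDS if b != "delta")

    def test_realized_relative_powers_match_weights(self):
        """Relative band powers of the generated signal stay within 2 %
        absolute of the configured weight profile."""
        cfg = CohortConfig(eeg_rate=500.0, suppression_max=0.0)
        cond = Condition(20.0, 0.8)
        rec, _ = simulate_eeg(cfg, cond, self._const_trace(cond, 33.0, start=0.0, end=20.0), seed=11)
        bp = compute_band_powers(rec, epoch_len=60.0)
        profile = cfg.profile_for(cond)
        for band, w in profile.items():
            assert bp.mean_relative(band) == pytest.approx(w, abs=0.02)

    def test_low_rate_rejected(self):
        cfg = CohortConfig()
        cfg.eeg_rate = 100.0
        cond = Condition(25.0, 0.8)
        with pytest.raises(ConfigError):
            simulate_eeg(cfg, cond, self._const_trace(cond, 34.0), seed=0)

    def test_suppression_fraction_bounds_and_midpoint(self):
        cfg = CohortConfig()
        f = suppression_fraction(cfg, np.array([20.0, cfg.suppression_t_half, 42.0]))
        assert 0.0 <= f[2] < f[1] < f[0] <= cfg.suppression_max
        assert f[1] == pytest.approx(cfg.suppression_max / 2)


class TestPhotometryGenerator:
    def test_zero_amplitude_gives_flat_baseline(self):
        cfg = CohortConfig(phot_amplitude=0.0, phot_drift_amp=0.0, phot_noise_sd=0.0)
        tr = simulate_photometry(cfg, {"LORR": 100.0}, seed=0)
        assert np.allclose(tr.f_raw, cfg.phot_baseline)

    def test_single_transient_peaks_at_kernel_peak_offset(self):
        """With one noise-free transient, argmax minus event time equals the
        closed-form double-exponential peak offset."""
        cfg = CohortConfig(phot_drift_amp=0.0, phot_noise_sd=0.0)
        tr = simulate_photometry(cfg, {"LORR": 200.0}, seed=0)
        t_peak = tr.times[np.argmax(tr.f_raw)]
        expected = kernel_peak_offset(cfg.phot_rise_tau, cfg.phot_decay_tau)
        assert t_peak - 200.0 == pytest.approx(expected, abs=1.0 / cfg.phot_rate)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            simulate_photometry(CohortConfig(), {}, seed=0)

    def test_non_positive_time_constants_rejected(self):
        cfg = CohortConfig()
        cfg.phot_rise_tau = -1.0
        with pytest.raises(ConfigError):
            simulate_photometry(cfg, {"LORR": 0.0}, seed=0)


class TestCohortAssembly:
    def test_same_seed_reproduces_cohort_exactly(self, small_config, tiny_cohort):
        other = generate_cohort(small_config)
        for a, b in zip(tiny_cohort.animals, other.animals):
            assert a.animal_id == b.animal_id
            np.testing.assert_array_equal(a.temperature.values, b.temperature.values)
            np.testing.assert_array_equal(a.eeg.samples, b.eeg.samples)
            np.testing.assert_array_equal(a.gate, b.gate)
            np.testing.assert_array_equal(a.photometry.f_raw, b.photometry.f_raw)
            assert a.truth == b.truth

    def test_cohort_size_and_gate_alignment(self, tiny_cohort, small_config):
        assert len(tiny_cohort.animals) == len(small_config.conditions) * small_config.n_per_group
        for a in tiny_cohort.animals:
            assert a.gate.size == a.eeg.samples.size

    def test_default_group_size_is_seven(self):
        assert CohortConfig().n_per_group == 7

    def test_duplicate_group_labels_rejected(self):
        cfg = CohortConfig(
            conditions=[Condition(25.0, 0.8, group_label="g"), Condition(25.0, 1.4, group_label="g")]
        )
        with pytest.raises(ConfigError):
            generate_cohort(cfg)

    def test_condition_validation(self):
        with pytest.raises(ConfigError):
            Condition(10.0, 0.8)  # chamber temperature out of range
        with pytest.raises(ConfigError):
            Condition(25.0, 5.0)  # dose out of range
        with pytest.raises(ConfigError):
            Condition(25.0, 0.8, intervention="activate",
                      intervention_onset=10.0, intervention_offset=5.0)
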