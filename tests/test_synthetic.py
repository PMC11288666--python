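"""Synthetic ERG generator: determinism, construction invariants, recovery."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ergkit import (
    CohortConfig,
    ERGRecording,
    FlashProtocol,
    FusionModel,
    GenotypeEffect,
    WaveformParams,
    compute_fff,
    extract_b_wave_metrics,
    metrics_table,
    power_spectrum,
    simulate_cohort,
    simulate_flash_response,
    simulate_flicker_series,
)
from ergkit.synthetic import noiseless_flash_signal


class TestFlashResponse:
    def test_zero_signal_zero_noise_is_flat_baseline(self, protocol):
        params = WaveformParams(a_amp=0.0, b_amp_fast=0.0, b_amp_slow=0.0,
                                noise_sd=0.0)
        rec = simulate_flash_response(params, protocol, 0.0)
        assert np.all(rec.voltage_uV == 0.0)

    def test_determinism_bit_identical(self, protocol):
        params = WaveformParams(seed=1234)
        a = simulate_flash_response(params, protocol, -1.0)
        b = simulate_flash_response(params, protocol, -1.0)
        assert np.array_equal(a.voltage_uV, b.voltage_uV)

    def test_different_seeds_differ(self, protocol):
        a = simulate_flash_response(WaveformParams(seed=1), protocol, 0.0)
        b = simulate_flash_response(WaveformParams(seed=2), protocol, 0.0)
        assert not np.array_equal(a.voltage_uV, b.voltage_uV)

    def test_attenuation_must_belong_to_protocol(self, protocol):
        with pytest.raises(ValueError, match="attenuation"):
            simulate_flash_response(WaveformParams(), protocol, -2.5)

    def test_superposition_matches_independent_kernel_sum(
        self, protocol, noiseless_params
    ):
        p = noiseless_params
        rec = simulate_flash_response(p, protocol, -1.0)
        t = np.arange(rec.n_samples) * 1000.0 / protocol.sampling_rate_hz
        u = t - protocol.stimulus_onset_ms
        irr = protocol.source_intensity * 0.1
        r = irr / (irr + p.half_sat_irradiance)  # hill exponent 1

        def bump(u, lat, tr, td):
            # independent evaluation of the rise-decay kernel
            z = np.where(u > lat, u - lat, np.nan)
            up = tr * math.log(1.0 + td / tr)
            pk = (1.0 - math.exp(-up / tr)) * math.exp(-up / td)
            out = (1.0 - np.exp(-z / tr)) * np.exp(-z / td) / pk
            return np.nan_to_num(out)

        def awave(u, lat, tau):
            tr = tau / 3.0
            z = np.where(u > lat, u - lat, np.nan)
            up = math.log(3.0) * tau * tr / (tau - tr)
            pk = math.exp(-up / tau) - math.exp(-up / tr)
            out = (np.exp(-z / tau) - np.exp(-z / tr)) / pk
            return np.nan_to_num(out)

        expected = (
            -p.a_amp * r * awave(u, p.a_latency, p.a_tau)
            + p.b_amp_fast * r * bump(u, p.b_latency_fast, p.rise_tau_fast, p.decay_tau)
            + p.b_amp_slow * r * bump(u, p.b_latency_slow, p.rise_tau_slow, p.decay_tau)
        )
        assert np.allclose(rec.voltage_uV, expected, rtol=1e-12, atol=1e-12)

    def test_single_component_amplitude_recovered_within_one_percent(self, protocol):
        params = WaveformParams(a_amp=0.0, b_amp_fast=150.0, b_amp_slow=0.0,
                                noise_sd=0.0, half_sat_irradiance=1e-3)
        rec = simulate_flash_response(params, protocol, 0.0)
        m = extract_b_wave_metrics(rec)
        assert m.amplitude_uV == pytest.approx(150.0, rel=0.01)

    def test_b_amplitude_monotone_in_irradiance(self, protocol, noiseless_params):
        amps = []
        for att in protocol.attenuations:
            rec = simulate_flash_response(noiseless_params, protocol, att)
            amps.append(extract_b_wave_metrics(rec).amplitude_uV)
        assert all(b >= a for a, b in zip(amps, amps[1:]))

    def test_metadata_records_ground_truth(self, protocol, noiseless_params):
        rec = simulate_flash_response(noiseless_params, protocol, 0.0)
        onset_idx = int(protocol.stimulus_onset_ms)
        assert rec.metadata["true_b_amplitude_uV"] == pytest.approx(
            float(np.max(rec.voltage_uV[onset_idx:]))
        )
        assert "seed" in rec.metadata
        assert rec.irradiance_uW_cm2 == pytest.approx(1874.4)

    def test_slow_latency_before_fast_rejected(self):
        with pytest.raises(ValueError, match="slow"):
            WaveformParams(b_latency_fast=100.0, b_latency_slow=90.0)


class TestFlickerSeries:
    def test_zero_gain_yields_pure_noise(self):
        params = WaveformParams(noise_sd=5.0)
        silent = simulate_flicker_series(
            params, FusionModel(response_gain=0.0), seed=3
        )
        noise_only = simulate_flicker_series(
            params, FusionModel(response_gain=0.0), seed=3
        )
        for a, b in zip(silent.recordings, noise_only.recordings):
            assert np.array_equal(a.voltage_uV, b.voltage_uV)
        # and the trains carry only the injected noise: sd close to noise_sd
        sds = [np.std(r.voltage_uV) for r in silent.recordings]
        assert np.allclose(sds, 5.0, rtol=0.2)

    def test_below_cutoff_train_is_periodic_at_stimulus_period(self):
        series = simulate_flicker_series(
            WaveformParams(noise_sd=0.0),
            FusionModel(cutoff_frequency=25.0),
            start_freq_hz=10.0, max_freq_hz=10.0, seed=0,
        )
        x = series.recordings[0].voltage_uV.astype(float)
        x = x - x.mean()
        steady = x[400:]  # skip the onset transient
        ac = np.correlate(steady, steady, mode="full")[steady.size - 1:]
        lag = 50 + int(np.argmax(ac[50:150]))  # search 50-150 ms
        assert lag == 100

    def test_dominant_nonzero_bin_is_the_stimulus_frequency(self):
        series = simulate_flicker_series(
            WaveformParams(noise_sd=0.0),
            FusionModel(cutoff_frequency=30.0),
            start_freq_hz=12.0, max_freq_hz=12.0, seed=0,
        )
        spec = power_spectrum(series.recordings[0])
        k = int(np.argmax(spec.power_uV2[1:])) + 1
        assert spec.frequency_hz[k] == pytest.approx(12.0)

    def test_ground_truth_cutoff_recorded(self):
        series = simulate_flicker_series(
            WaveformParams(), FusionModel(cutoff_frequency=18.0), seed=0
        )
        assert series.metadata["true_cutoff_hz"] == pytest.approx(18.0)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            simulate_flicker_series(WaveformParams(), FusionModel(), step_hz=0.0)

    def test_sweep_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_flicker_series(
                WaveformParams(), FusionModel(), max_freq_hz=600.0
            )

    def test_end_to_end_cutoff_recovery(self):
        series = simulate_flicker_series(
            WaveformParams(), FusionModel(cutoff_frequency=25.0), seed=7
        )
        assert abs(compute_fff(series).fff_hz - 25.0) <= 1.0


class TestCohort:
    def test_determinism(self):
        cfg = CohortConfig(eyes_per_genotype=2, master_seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for ra, rb in zip(a.recordings, b.recordings):
            assert np.array_equal(ra.voltage_uV, rb.voltage_uV)

    def test_layout_and_provenance(self, protocol):
        cfg = CohortConfig(eyes_per_genotype=2, master_seed=1)
        cohort = simulate_cohort(cfg, protocol)
        assert len(cohort.recordings) == len(cfg.genotypes) * 2 * protocol.n_intensities
        seen = {(r.genotype, r.eye_id, r.metadata["attenuation_log"])
                for r in cohort.recordings}
        assert len(seen) == len(cohort.recordings)  # each cell appears once
        assert all("seed" in r.metadata for r in cohort.recordings)

    def test_noiseless_half_amplitude_scale_recovered_exactly(self):
        genotypes = {
            "WT": GenotypeEffect(),
            "half": GenotypeEffect(amplitude_scale_fast=0.5, amplitude_scale_slow=0.5),
        }
        cfg = CohortConfig(
            genotypes=genotypes, eyes_per_genotype=2, eye_amplitude_cv=0.0,
            eye_latency_sd_ms=0.0, master_seed=0,
            base_params=WaveformParams(a_amp=0.0, noise_sd=0.0),
        )
        cohort = simulate_cohort(cfg)
        table = metrics_table(cohort.recordings)
        mean = table.groupby("genotype")["amplitude_uV"].mean()
        assert mean["half"] / mean["WT"] == pytest.approx(0.5, rel=1e-9)

    def test_noiseless_latency_shift_recovered_within_one_sample(self, protocol):
        shift = 15.0
        genotypes = {"WT": GenotypeEffect(),
                     "late": GenotypeEffect(latency_shift_ms=shift)}
        cfg = CohortConfig(
            genotypes=genotypes, eyes_per_genotype=2, eye_amplitude_cv=0.0,
            eye_latency_sd_ms=0.0, master_seed=0,
            base_params=WaveformParams(noise_sd=0.0),
        )
        table = metrics_table(simulate_cohort(cfg, protocol).recordings)
        mean = table.groupby("genotype")["implicit_time_ms"].mean()
        dt = 1000.0 / protocol.sampling_rate_hz
        assert mean["late"] - mean["WT"] == pytest.approx(shift, abs=dt)

    def test_empty_genotype_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CohortConfig(genotypes={})

    def test_single_eye_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(eyes_per_genotype=1)
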