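"""Synthetic larval-zebrafish ERG generator with known ground truth.

Emulates the data the analysis chain consumes: flash ERGs (negative a-wave
followed by a positive b-wave over a five-step log-attenuation intensity
series), flicker trains with a hard temporal-fusion cutoff, genotype cohorts
with configurable effect sizes, and white-light source spectra.

The waveform model is phenomenological, not mechanistic: the b-wave is the
superposition of a fast (metabotropic-like) and a slow, later-onset
(glutamate-transporter-like) rise–decay component, each scaled by a
Naka–Rushton saturating function of the stimulus irradiance, on top of a
brief negative a-deflection.  Knocking the slow component out and shifting
the b-wave onset reproduce the amplitude-reduction and implicit-time-shift
phenotypes the analysis is meant to detect.  At 5 dpf the responses are
treated as pure cone responses; no rod pathway is simulated.

All randomness flows from explicit seeds through `numpy.random.SeedSequence`
spawn keys, so every trace, eye, and cohort is exactly reproducible and the
per-trace seed is recorded in the output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .photometry import DEFAULT_ATTENUATIONS, SpectralIrradiance, integrate_spectrum
from .waveform import ERGRecording
from .flicker import FlickerSeries

#: Rolloff values below this are clipped to zero: the fusion cutoff is hard.
_FUSION_CLIP = 1e-3
#: Fixed rise/decay ratio of the difference-of-exponentials a-wave kernel.
_A_RISE_RATIO = 3.0

SOURCE1_INTENSITY_UW_CM2 = 1874.4    # ZEISS XBO 75 W arc, 189-800 nm
SOURCE2_INTENSITY_UW_CM2 = 12652.8   # HPX-2000 xenon source, 189-800 nm


# ---------------------------------------------------------------------------
# protocols and parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlashProtocol:
    """Flash stimulation protocol and recording layout.

    Five white-light flashes of increasing intensity (log −4 … log 0 of the
    source intensity), 100 ms flashes, 7 s inter-stimulus interval.  The
    recording layout (1 kHz sampling, onset at 100 ms, 1 s traces) puts the
    50 ms baseline window fully before the stimulus.
    """

    attenuations: tuple[float, ...] = DEFAULT_ATTENUATIONS
    stimulus_duration_ms: float = 100.0
    inter_stimulus_interval_ms: float = 7000.0
    source_intensity: float = SOURCE1_INTENSITY_UW_CM2
    sampling_rate_hz: float = 1000.0
    stimulus_onset_ms: float = 100.0
    trace_duration_ms: float = 1000.0

    def __post_init__(self) -> None:
        atts = self.attenuations
        if not atts:
            raise ValueError("protocol needs at least one attenuation step")
        if not all(a <= 0 for a in atts):
            raise ValueError("attenuations must be <= 0 log units")
        if not all(b > a for a, b in zip(atts, atts[1:])):
            raise ValueError("attenuations must be strictly ascending")
        if self.stimulus_duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.trace_duration_ms <= self.stimulus_onset_ms:
            raise ValueError("trace must extend beyond the stimulus onset")

    @property
    def n_intensities(self) -> int:
        return len(self.attenuations)


@dataclass(frozen=True)
class WaveformParams:
    """Ground-truth flash-response shape parameters (one eye).

    Amplitudes are the component peaks at saturating irradiance, μV; the
    irradiance dependence is Naka–Rushton,
    R(I) = I^n / (I^n + I50^n).  Latencies are measured from light onset.
    The slow component onsets later than the fast one, so removing or
    rescaling it shifts the measured b-wave onset (implicit time).
    """

    a_amp: float = 15.0            # μV, a-wave trough depth
    a_latency: float = 20.0        # ms
    a_tau: float = 12.0            # ms, a-wave decay time constant
    b_amp_fast: float = 120.0      # μV, metabotropic-like component
    b_amp_slow: float = 60.0       # μV, transporter-like component
    b_latency_fast: float = 110.0  # ms
    b_latency_slow: float = 135.0  # ms
    rise_tau_fast: float = 40.0    # ms
    rise_tau_slow: float = 60.0    # ms
    decay_tau: float = 250.0       # ms
    half_sat_irradiance: float = 5.0   # μW cm⁻², Naka–Rushton I50
    hill_exponent: float = 1.0
    noise_sd: float = 5.0          # μV, additive white Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_tau", "rise_tau_fast", "rise_tau_slow", "decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a_amp", "b_amp_fast", "b_amp_slow", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.b_latency_slow < self.b_latency_fast:
            raise ValueError("the slow b component must onset at or after the fast one")
        if self.hill_exponent <= 0:
            raise ValueError("hill exponent must be positive")
        if self.half_sat_irradiance <= 0:
            raise ValueError("half-saturation irradiance must be positive")


@dataclass(frozen=True)
class FusionModel:
    """Ground-truth temporal fusion of the flicker response.

    The periodic-response gain rolls off logistically around
    ``cutoff_frequency`` and is clipped to exactly zero once below 0.1% of
    its maximum, giving a hard fusion cutoff.  The unit response to a single
    flash is a fast rise–decay kernel (cone-driven flicker kinetics).
    """

    cutoff_frequency: float = 25.0   # Hz, ground-truth FFF
    rolloff_sharpness: float = 6.0   # per Hz
    response_gain: float = 100.0     # μV, unit-response peak below cutoff
    rise_tau_ms: float = 3.0
    decay_tau_ms: float = 12.0

    def __post_init__(self) -> None:
        if self.response_gain < 0:
            raise ValueError("response gain must be non-negative")
        if self.rolloff_sharpness <= 0:
            raise ValueError("rolloff sharpness must be positive")
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise ValueError("unit-response time constants must be positive")

    def rolloff(self, frequency_hz: np.ndarray | float) -> np.ndarray | float:
        """Gain multiplier in [0, 1]; exactly 0 well above the cutoff."""
        r = 1.0 / (1.0 + np.exp(
            self.rolloff_sharpness * (np.asarray(frequency_hz, float) - self.cutoff_frequency)
        ))
        return np.where(r < _FUSION_CLIP, 0.0, r)


@dataclass(frozen=True)
class GenotypeEffect:
    """Per-genotype modifiers relative to the wild-type waveform."""

    amplitude_scale_fast: float = 1.0
    amplitude_scale_slow: float = 1.0
    amplitude_scale_a: float = 1.0
    latency_shift_ms: float = 0.0    # applied to both b-wave latencies

    def __post_init__(self) -> None:
        for name in ("amplitude_scale_fast", "amplitude_scale_slow", "amplitude_scale_a"):
            s = getattr(self, name)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def default_genotype_effects() -> dict[str, GenotypeEffect]:
    """Wild type plus the three knockout phenotypes the cohorts emulate.

    *eaat5b−/−*: slow component lost, b-wave onset earlier (shorter implicit
    time).  *eaat7−/−*: onset delayed.  Double KO: slow component lost, fast
    component reduced, onset earlier.
    """
    return {
        "WT": GenotypeEffect(),
        "eaat5b_ko": GenotypeEffect(amplitude_scale_slow=0.0, latency_shift_ms=-20.0),
        "eaat7_ko": GenotypeEffect(latency_shift_ms=15.0),
        "double_ko": GenotypeEffect(
            amplitude_scale_fast=0.7, amplitude_scale_slow=0.0, latency_shift_ms=-20.0
        ),
    }


@dataclass
class CohortConfig:
    """A simulated multi-eye, multi-genotype flash-ERG experiment."""

    genotypes: Mapping[str, GenotypeEffect] = field(default_factory=default_genotype_effects)
    eyes_per_genotype: int = 10
    eye_amplitude_cv: float = 0.15   # multiplicative eye-to-eye amplitude spread
    eye_latency_sd_ms: float = 5.0   # additive eye-to-eye latency jitter
    master_seed: int = 0
    base_params: WaveformParams = field(default_factory=WaveformParams)

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("genotype list must not be empty")
        if self.eyes_per_genotype < 2:
            raise ValueError("at least two eyes per genotype are required")
        if self.eye_amplitude_cv < 0 or self.eye_latency_sd_ms < 0:
            raise ValueError("eye-level variability must be non-negative")


@dataclass
class CohortDataset:
    """All recordings of one simulated cohort, with full provenance."""

    recordings: list[ERGRecording]
    config: CohortConfig
    protocol: FlashProtocol


# ---------------------------------------------------------------------------
# waveform kernels (phenomenological, unit peak)
# ---------------------------------------------------------------------------

def rise_decay_kernel(
    t_ms: np.ndarray, latency_ms: float, rise_tau_ms: float, decay_tau_ms: float
) -> np.ndarray:
    """Smooth unimodal kernel (1 − e^{−u/τr}) e^{−u/τd}, normalized to peak 1.

    ``u = t − latency``; zero for ``t <= latency``.  The analytic peak sits at
    ``u* = τr · ln(1 + τd/τr)``.
    """
    u = np.asarray(t_ms, float) - latency_ms
    out = np.zeros_like(u)
    m = u > 0
    u_peak = rise_tau_ms * math.log1p(decay_tau_ms / rise_tau_ms)
    peak = (1.0 - math.exp(-u_peak / rise_tau_ms)) * math.exp(-u_peak / decay_tau_ms)
    out[m] = (1.0 - np.exp(-u[m] / rise_tau_ms)) * np.exp(-u[m] / decay_tau_ms) / peak
    return out


def a_wave_kernel(t_ms: np.ndarray, latency_ms: float, tau_ms: float) -> np.ndarray:
    """Difference-of-exponentials kernel, unit peak, decay τ and rise τ/3."""
    tau_r = tau_ms / _A_RISE_RATIO
    u = np.asarray(t_ms, float) - latency_ms
    out = np.zeros_like(u)
    m = u > 0
    u_peak = math.log(_A_RISE_RATIO) * tau_ms * tau_r / (tau_ms - tau_r)
    peak = math.exp(-u_peak / tau_ms) - math.exp(-u_peak / tau_r)
    out[m] = (np.exp(-u[m] / tau_ms) - np.exp(-u[m] / tau_r)) / peak
    return out


def naka_rushton(irradiance: float, half_sat: float, exponent: float) -> float:
    """Saturating intensity-response function R(I) = Iⁿ / (Iⁿ + I50ⁿ)."""
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if irradiance == 0:
        return 0.0
    ratio = (half_sat / irradiance) ** exponent
    return 1.0 / (1.0 + ratio)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed from a parent seed and a spawn key."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def noiseless_flash_signal(
    params: WaveformParams, protocol: FlashProtocol, attenuation: float
) -> np.ndarray:
    """Deterministic part of a flash response on the protocol's time grid."""
    n = int(round(protocol.trace_duration_ms * protocol.sampling_rate_hz / 1000.0))
    t = np.arange(n) * 1000.0 / protocol.sampling_rate_hz
    irr = protocol.source_intensity * 10.0 ** attenuation
    r = naka_rushton(irr, params.half_sat_irradiance, params.hill_exponent)
    rel = t - protocol.stimulus_onset_ms
    a = -params.a_amp * r * a_wave_kernel(rel, params.a_latency, params.a_tau)
    b = (
        params.b_amp_fast * r
        * rise_decay_kernel(rel, params.b_latency_fast, params.rise_tau_fast, params.decay_tau)
        + params.b_amp_slow * r
        * rise_decay_kernel(rel, params.b_latency_slow, params.rise_tau_slow, params.decay_tau)
    )
    return a + b


def simulate_flash_response(
    params: WaveformParams,
    protocol: FlashProtocol,
    attenuation: float,
    genotype: str = "",
    eye_id: str = "",
) -> ERGRecording:
    """One flash ERG trace at the given log attenuation.

    The trace is the noiseless kernel superposition plus white Gaussian noise
    (sd ``params.noise_sd``), with all ground-truth quantities — irradiance,
    Naka–Rushton response fraction, scaled component amplitudes, and the
    noiseless b-wave peak within the analysis window — stored in metadata.
    """
    if not any(math.isclose(attenuation, a, abs_tol=1e-9) for a in protocol.attenuations):
        raise ValueError(
            f"attenuation {attenuation} is not a step of the protocol "
            f"{protocol.attenuations}"
        )
    n = int(round(protocol.trace_duration_ms * protocol.sampling_rate_hz / 1000.0))
    min_n = int(round(protocol.stimulus_onset_ms * protocol.sampling_rate_hz / 1000.0)) + 2
    if n < min_n:
        raise ValueError("trace too short for the stimulus onset and analysis window")
    signal = noiseless_flash_signal(params, protocol, attenuation)
    irr = protocol.source_intensity * 10.0 ** attenuation
    r = naka_rushton(irr, params.half_sat_irradiance, params.hill_exponent)
    trace_seed = _child_seed(params.seed, int(round(-attenuation * 1000)))
    rng = np.random.default_rng(trace_seed)
    noise = rng.normal(0.0, params.noise_sd, signal.size) if params.noise_sd > 0 else 0.0
    onset_idx = int(round(protocol.stimulus_onset_ms * protocol.sampling_rate_hz / 1000.0))
    metadata = {
        "attenuation_log": float(attenuation),
        "response_fraction": r,
        "a_amp_scaled_uV": params.a_amp * r,
        "b_amp_fast_scaled_uV": params.b_amp_fast * r,
        "b_amp_slow_scaled_uV": params.b_amp_slow * r,
        "true_b_amplitude_uV": float(np.max(signal[onset_idx:])),
        "b_latency_fast_ms": params.b_latency_fast,
        "b_latency_slow_ms": params.b_latency_slow,
        "noise_sd_uV": params.noise_sd,
        "seed": trace_seed,
    }
    return ERGRecording(
        voltage_uV=signal + noise,
        sampling_rate_hz=protocol.sampling_rate_hz,
        stimulus_onset_ms=protocol.stimulus_onset_ms,
        stimulus_duration_ms=protocol.stimulus_duration_ms,
        irradiance_uW_cm2=irr,
        genotype=genotype,
        eye_id=eye_id,
        metadata=metadata,
    )


def simulate_flash_series(
    params: WaveformParams,
    protocol: FlashProtocol = FlashProtocol(),
    genotype: str = "",
    eye_id: str = "",
) -> list[ERGRecording]:
    """One eye's full intensity series (one trace per attenuation step)."""
    return [
        simulate_flash_response(params, protocol, a, genotype=genotype, eye_id=eye_id)
        for a in protocol.attenuations
    ]


def simulate_flicker_series(
    params: WaveformParams,
    fusion: FusionModel,
    start_freq_hz: float = 7.0,
    step_hz: float = 1.0,
    max_freq_hz: float = 40.0,
    pulse_duration_ms: float = 15.0,
    record_duration_ms: float = 2000.0,
    sampling_rate_hz: float = 1000.0,
    seed: int = 0,
) -> FlickerSeries:
    """A flicker frequency sweep from one eye.

    Each train superposes the fusion model's unit response at the stimulus
    times of its frequency, with the response amplitude multiplied by the
    fusion rolloff (zero above the hard cutoff), plus white Gaussian noise
    with ``params.noise_sd``.  The ground-truth cutoff is recorded.
    """
    if step_hz <= 0:
        raise ValueError("frequency step must be positive")
    if start_freq_hz > max_freq_hz:
        raise ValueError("start frequency must not exceed the sweep maximum")
    if max_freq_hz >= sampling_rate_hz / 2.0:
        raise ValueError("sweep maximum must stay below the Nyquist frequency")
    if record_duration_ms < 3 * 1000.0 / start_freq_hz:
        raise ValueError("recording must cover several stimulus periods")
    n = int(round(record_duration_ms * sampling_rate_hz / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate_hz
    n_freq = int(math.floor((max_freq_hz - start_freq_hz) / step_hz + 1e-9)) + 1
    freqs = tuple(start_freq_hz + i * step_hz for i in range(n_freq))
    # evaluate the unit kernel only over its effective support
    support_ms = fusion.rise_tau_ms + 10.0 * fusion.decay_tau_ms
    recordings = []
    for i, f in enumerate(freqs):
        amp = fusion.response_gain * float(fusion.rolloff(f))
        x = np.zeros(n)
        if amp > 0:
            period = 1000.0 / f
            for t0 in np.arange(0.0, record_duration_ms, period):
                i0 = int(math.ceil(t0 * sampling_rate_hz / 1000.0))
                i1 = min(n, int(math.ceil((t0 + support_ms) * sampling_rate_hz / 1000.0)))
                if i0 >= n:
                    break
                x[i0:i1] += amp * rise_decay_kernel(
                    t[i0:i1] - t0, 0.0, fusion.rise_tau_ms, fusion.decay_tau_ms
                )
        rng = np.random.default_rng(_child_seed(seed, i))
        if params.noise_sd > 0:
            x = x + rng.normal(0.0, params.noise_sd, n)
        recordings.append(
            ERGRecording(
                voltage_uV=x,
                sampling_rate_hz=sampling_rate_hz,
                stimulus_onset_ms=0.0,
                stimulus_duration_ms=pulse_duration_ms,
                metadata={
                    "stimulus_frequency_hz": f,
                    "true_cutoff_hz": fusion.cutoff_frequency,
                    "seed": _child_seed(seed, i),
                },
            )
        )
    return FlickerSeries(
        frequencies_hz=freqs,
        recordings=recordings,
        pulse_duration_ms=pulse_duration_ms,
        metadata={"true_cutoff_hz": fusion.cutoff_frequency, "seed": seed},
    )


def simulate_cohort(
    config: CohortConfig, protocol: FlashProtocol = FlashProtocol()
) -> CohortDataset:
    """Simulate one flash series per eye per genotype.

    Eye-level variability: a multiplicative amplitude factor (normal with CV
    ``eye_amplitude_cv``, truncated at 0.05) applied to all components, and a
    shared additive latency jitter on both b-wave latencies.  Genotype
    effects rescale individual components and shift the b-wave onset.  Every
    eye's seed derives from ``master_seed`` via a fixed spawn-key rule and is
    recorded in the trace metadata.
    """
    recordings: list[ERGRecording] = []
    base = config.base_params
    for g_idx, (genotype, effect) in enumerate(config.genotypes.items()):
        for eye_idx in range(config.eyes_per_genotype):
            eye_rng = np.random.default_rng(
                _child_seed(config.master_seed, g_idx, eye_idx, 1)
            )
            amp_factor = (
                max(float(eye_rng.normal(1.0, config.eye_amplitude_cv)), 0.05)
                if config.eye_amplitude_cv > 0 else 1.0
            )
            lat_jitter = (
                float(eye_rng.normal(0.0, config.eye_latency_sd_ms))
                if config.eye_latency_sd_ms > 0 else 0.0
            )
            shift = effect.latency_shift_ms + lat_jitter
            eye_params = replace(
                base,
                a_amp=base.a_amp * effect.amplitude_scale_a * amp_factor,
                b_amp_fast=base.b_amp_fast * effect.amplitude_scale_fast * amp_factor,
                b_amp_slow=base.b_amp_slow * effect.amplitude_scale_slow * amp_factor,
                b_latency_fast=base.b_latency_fast + shift,
                b_latency_slow=base.b_latency_slow + shift,
                seed=_child_seed(config.master_seed, g_idx, eye_idx, 2),
            )
            eye_id = f"{genotype}-{eye_idx:02d}"
            for rec in simulate_flash_series(eye_params, protocol, genotype, eye_id):
                rec.metadata.update(
                    eye_amplitude_factor=amp_factor,
                    eye_latency_jitter_ms=lat_jitter,
                    genotype_latency_shift_ms=effect.latency_shift_ms,
                )
                recordings.append(rec)
    return CohortDataset(recordings=recordings, config=config, protocol=protocol)


# ---------------------------------------------------------------------------
# source spectra
# ---------------------------------------------------------------------------

def spectrum_shape(shape: str, wavelength_nm: np.ndarray) -> np.ndarray:
    """Un-normalized spectral shape on a wavelength grid.

    ``rectangular`` and ``triangular`` are analytic references; ``xenon``
    is a smooth multi-peak continuum resembling a xenon arc (synthetic —
    the real source spectra are not published).
    """
    w = np.asarray(wavelength_nm, float)
    if shape == "rectangular":
        return np.ones_like(w)
    if shape == "triangular":
        mid = 0.5 * (w[0] + w[-1])
        half = 0.5 * (w[-1] - w[0])
        return np.clip(1.0 - np.abs(w - mid) / half, 0.0, None)
    if shape == "xenon":
        v = 0.35 * np.exp(-(((w - 420.0) / 180.0) ** 2))
        for center, width, height in (
            (250.0, 20.0, 0.25), (450.0, 15.0, 1.0), (475.0, 12.0, 0.8),
            (530.0, 20.0, 0.55), (650.0, 25.0, 0.35), (760.0, 18.0, 0.3),
        ):
            v = v + height * np.exp(-(((w - center) / width) ** 2))
        return v
    raise ValueError(f"unknown spectrum shape {shape!r}")


def simulate_spectrum(
    shape: str,
    total_intensity: float,
    wavelength_grid_nm: Optional[np.ndarray] = None,
    label: str = "",
) -> SpectralIrradiance:
    """A non-negative source spectrum normalized to a requested intensity.

    The spectrum is scaled so that :func:`ergkit.photometry.integrate_spectrum`
    over 189–800 nm returns ``total_intensity`` (well within 0.1%).
    """
    if total_intensity <= 0:
        raise ValueError("total intensity must be positive")
    if wavelength_grid_nm is None:
        wavelength_grid_nm = np.arange(189.0, 801.0, 1.0)
    w = np.asarray(wavelength_grid_nm, float)
    if w[0] < 189.0 - 1e-9 or w[-1] > 800.0 + 1e-9:
        raise ValueError("wavelength grid must lie within 189-800 nm")
    v = spectrum_shape(shape, w)
    raw = SpectralIrradiance(w, v, label=label or f"synthetic-{shape}")
    area = integrate_spectrum(raw)
    if area <= 0:
        raise ValueError("degenerate spectrum shape on this grid")
    return SpectralIrradiance(w, v * (total_intensity / area),
                              label=label or f"synthetic-{shape}")
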