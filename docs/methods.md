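# Methods

This note documents the models and numerical choices behind `ergkit`: what
the analysis operations compute, what the synthetic generator emulates (and
what it does not), and where the design was genuinely open.

## Flash ERG quantification

A recording is a uniformly sampled voltage trace (μV) starting at t = 0 with
light onset at a known time (default 100 ms into a 1 s trace at 1 kHz).

**Baseline.** Arithmetic mean of all samples with t < 50 ms. With the default
layout this window is entirely pre-stimulus.

**b-wave amplitude.** Maximum voltage within a search window after onset
(default [onset, onset + 300 ms]) minus the baseline; ties broken by the
earliest time. Amplitude is baseline-to-peak, not a-trough-to-peak: the
a-wave trough does not enter the measurement.

**Implicit time.** On the baseline-subtracted trace, `t20` and `t80` are the
times of the *last* upward crossings of 0.2·A and 0.8·A before the peak,
each located by linear interpolation between the bracketing samples. Taking
the last crossing selects the final rising limb into the peak, so neither
noise excursions nor the a-wave recovery limb can be selected. The line
through (t20, 0.2·A) and (t80, 0.8·A) crosses the baseline level at
`t20 − (t80 − t20)/3`; the implicit time is that intersection minus the
onset time. The "axis" the line is intersected with is the baseline level of
the recording (equivalently, zero after baseline subtraction), not absolute
zero volts.

**Validity filter.** Implicit times outside [50, 230] ms are flagged
(`below_filter` / `above_filter`) and excluded listwise from statistics;
boundary values are kept. Extraction failures carry their own reasons
(`no_crossing`, `nonpositive_amplitude`, `degenerate_rise`). No smoothing or
detrending is applied before metric extraction.

## Flicker ERG and fusion frequency

Each 2 s train is mean-detrended (no drift removal) and transformed with an
un-windowed real FFT to a one-sided power spectrum over 0–50 Hz. The
convention: a sinusoid of amplitude *a* with an integer number of cycles has
power a²/2 at its bin, and the one-sided power summed over all bins equals
the signal's mean square (Parseval). With 2 s records the resolution is
0.5 Hz, so every integer-Hz stimulus falls exactly on a bin and is leak-free
apart from the onset transient; no taper is applied by default.

**Resolvability.** Frequency f is resolvable when the power at its bin
exceeds θ× a noise floor, with the floor the median power of the in-band
bins after excluding DC and ±1 bin around the fundamental and each harmonic.
Harmonics are excluded from the floor but never counted as evidence. For
white noise the bin powers are approximately i.i.d. exponential, so the
false-positive rate at threshold θ×median is ≈ 2^−θ; the default θ = 5 puts
it near 3%, and the measured rate is asserted ≤ 5% per frequency. θ and the
exclusion radius are configurable.

**FFF rule.** Default is the contiguity rule — the last resolvable frequency
before the first unresolvable one — which is robust to isolated spurious
peaks above fusion; the literal "highest resolvable overall" is available as
a mode and both values are reported. If every swept frequency is resolvable
the result is censored at the sweep maximum; if none is, the FFF is NaN
(below-range sentinel).

## Photometry

Source intensity is the trapezoidal area under the spectral-irradiance curve
on its native (possibly non-uniform) wavelength grid, restricted to
189–800 nm with linear interpolation at the clip boundaries — exact for
piecewise-linear spectra. The stimulus ladder applies decadic attenuation
I₀·10^a for log units a ≤ 0; attenuation is assumed spectrally neutral.
From the two sources used (1874.4 and 12 652.8 μW cm⁻²) the dimmest steps at
log −4 are ≈ 0.19 and ≈ 1.3 μW cm⁻².

## Cohort statistics

Per intensity step and per mutant genotype, the comparison against the
reference group uses a two-tailed two-sample t-test. Student's
pooled-variance variant is the default (the variant used is always recorded
in the output; Welch is available) and zero-variance cells raise rather than
return a meaningless p. Box summaries use Tukey hinges (medians of the
sorted halves, the middle observation included in both halves when n is odd)
with whiskers at the data minimum and maximum — no 1.5·IQR fencing. Invalid
metrics are excluded listwise and exclusion counts reported; no
multiple-testing correction is applied across intensities. Eyes are treated
as independent units.

## Synthetic generator

The generator produces data with the statistical structure the analyses
assume, with every ground-truth value recorded in metadata.

**Flash waveform.** The noiseless response is a superposition of three
phenomenological kernels, each normalized to unit peak:

- a-wave: −a_amp · (e^{−u/τ} − e^{−3u/τ}) (difference of exponentials,
  default trough 15 μV, latency 20 ms, τ = 12 ms);
- two b-wave components with kernel (1 − e^{−u/τr}) e^{−u/τd}: a fast
  "metabotropic-like" component (120 μV, latency 110 ms, τr = 40 ms) and a
  slow, later-onset "transporter-like" component (60 μV, latency 135 ms,
  τr = 60 ms), shared decay τd = 250 ms.

Component amplitudes are scaled by a Naka–Rushton function
R(I) = Iⁿ/(Iⁿ + I50ⁿ) of the attenuated irradiance (defaults I50 = 5 μW cm⁻²,
n = 1 — the half-saturation sits between the log −3 and log −2 steps of
source 1, giving a graded five-step series). Noise is additive white
Gaussian (default sd 5 μV). The defaults put the wild-type implicit time
near 106 ms, inside the 50–230 ms validity band and in the range reported
for larval flash ERGs; a −20 ms genotype shift stays valid. Kernels are
phenomenological: no conductance/ODE model of mGluR6–TRPM1 or transporter
gating, and no rod pathway (larval responses are treated as pure cone
responses).

**Genotype effects.** Per-genotype multipliers in [0, 1] on each component's
amplitude plus a latency shift applied to *both* b-wave latencies (a whole
b-wave onset shift), so a shift of Δ moves the measured implicit time by
exactly Δ — the shift-equivariance property the recovery tests rely on.
Eye-level variability is a multiplicative amplitude factor (CV 0.15,
truncated at 0.05) and an additive latency jitter (sd 5 ms) shared by both
components.

**Flicker trains.** Unit responses (fast rise–decay kernel, τr = 3 ms,
τd = 12 ms — cone-driven flicker kinetics, much faster than the flash
b-wave so the stimulus frequency, not the kernel low-pass, limits detection)
are superposed at the stimulus times of each frequency. The periodic
amplitude is response_gain × a logistic rolloff in frequency around the
ground-truth cutoff (sharpness 6 Hz⁻¹), clipped to exactly zero once below
10⁻³ — a hard fusion cutoff with a narrow soft shoulder. A purely logistic
rolloff never reaches zero, which would make noiseless resolvability
scale-invariant and fusion undetectable without noise.

**Spectra.** Rectangular and triangular analytic shapes plus a smooth
multi-peak "xenon-like" continuum (Gaussian lines ≥ 12 nm wide on a broad
base; synthetic — the real source spectra are unpublished), normalized on
the provided grid so the 189–800 nm integral equals the requested intensity.

**Seeding.** All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawn keys (genotype index, eye index, stream
tag; attenuation index within an eye), so cohorts are bit-reproducible and
every trace records its own derived seed.

## What the simulations do and do not show

Passing recovery and calibration tests shows the chain is correct *under the
generator's assumptions*: additive white Gaussian noise, smooth unimodal
kernels, neutral attenuation, independent eyes, and exactly grid-aligned
stimulus frequencies. Real recordings add drift, line interference,
amplifier filtering, eye-movement artefacts, and correlated eyes within an
animal — none of which are emulated, and each of which can degrade the
metrics in ways these tests cannot detect. The optional Hann window and
denoising hooks exist for such data but are off by default and untested
against real traces.

## Problem sizes and numerical choices

Monte-Carlo checks use: 100 seeds per fusion cutoff (15/25/35 Hz) for FFF
recovery; 1000 white-noise trains for the false-positive rate; 1000 null
cohorts (two genotypes × 6 eyes at one intensity) for the type-I error of
the full pipeline; 150 randomized latencies for the validity filter. These
sizes put the binomial standard error of each rate well inside the asserted
bands. Crossing times use linear interpolation (error far below 0.1 ms at
1 kHz for physiological rise times); the uniform-grid check on file read
uses 10⁻⁶ relative tolerance; written floats carry 9 significant digits so
outputs are byte-reproducible.

## Known limitations

- The peak-presence criterion is parameterized (θ, radius), not a claim
  about any particular historical analysis; absolute-power thresholds are
  not implemented.
- The FFF is only defined on the swept grid; censoring at the sweep top is
  reported but not extrapolated.
- Student's t-test on FFF values treats a discrete (1 Hz-grid) quantity as
  continuous; at high signal-to-noise the within-group variance can
  degenerate, which the code surfaces as an explicit error rather than a p
  value.
- No radiometric-to-photometric conversion, oscillatory-potential analysis,
  a-wave quantification, or mixed-effects modelling of repeated eyes.
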