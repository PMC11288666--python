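# ergkit

Quantification of larval zebrafish electroretinograms (ERGs): flash b-wave
amplitude and implicit time, flicker fusion frequency (FFF), light-source
photometry, and cohort-level genotype comparisons — together with a synthetic
ERG generator with recorded ground truth, so the whole analysis chain is
testable end to end without any recordings.

The package is aimed at visual neurophysiologists comparing outer-retinal
function between wild-type and mutant animals (e.g. glutamate-transporter
knockouts), where the readouts are the ON-bipolar-cell-driven b-wave and the
temporal resolution of vision.

## What it computes

**Flash ERG (b-wave).** For a corneal voltage trace with light onset at a
known time:

- baseline `B` = mean of the first 50 ms (pre-stimulus);
- b-wave amplitude `A` = max of the trace within a post-onset search window
  minus `B` (baseline-to-peak, a proxy for ON-bipolar cell depolarization);
- implicit time (b-wave onset): find the times `t20`, `t80` where the
  baseline-subtracted trace last rises through `0.2·A` and `0.8·A` before the
  peak, draw the straight line through those two points, and intersect it
  with the baseline level. In closed form,

  `IT = t20 − (t80 − t20)/3 − t_onset`.

  Implicit times below 50 ms or above 230 ms are flagged invalid and excluded
  from statistics.

**Flicker ERG (FFF).** Each 2 s train recorded at a stimulus frequency `f`
(sweep from 7 Hz in 1 Hz steps) is mean-detrended and transformed to a
one-sided power spectrum over 0–50 Hz (0.5 Hz bins, so integer-Hz stimuli are
leak-free). `f` is *resolvable* when the power at its bin exceeds θ× the
median in-band noise floor (θ = 5 by default; the fundamental's harmonics are
excluded from the floor but never counted as evidence). The FFF is the last
resolvable frequency before the first unresolvable one (a "highest resolvable
overall" mode is also reported).

**Photometry.** Source intensity = trapezoidal area under the measured
spectral-irradiance curve between 189 and 800 nm; the stimulus ladder applies
decadic attenuation `I(a) = I₀·10^a` for `a = −4 … 0` log units.

**Cohort statistics.** Per intensity step, mutant vs wild-type two-tailed
two-sample t-tests (Student pooled-variance by default, Welch optional) and
box-and-whisker summaries with Tukey-hinge quartiles and whiskers at the data
extremes.

**Synthetic data.** Flash responses are a negative a-wave plus a
two-component (fast + slow, later-onset) b-wave, each a smooth rise–decay
kernel scaled by a Naka–Rushton function of irradiance, with white Gaussian
noise; flicker trains superpose a fast unit response at the stimulus times
with a hard fusion cutoff; genotype effects rescale components and shift the
b-wave onset. Every ground-truth value is recorded in trace metadata and all
randomness is seed-derived and reproducible. See `docs/methods.md`.

## Worked example

```python
from ergkit import (FlashProtocol, FusionModel, WaveformParams,
                    compute_fff, extract_b_wave_metrics,
                    simulate_flash_response, simulate_flicker_series)

rec = simulate_flash_response(WaveformParams(seed=42), FlashProtocol(), -1.0)
m = extract_b_wave_metrics(rec)
print(f"irradiance  : {rec.irradiance_uW_cm2:.2f} uW cm-2")
print(f"baseline    : {m.baseline_uV:.2f} uV")
print(f"amplitude   : {m.amplitude_uV:.2f} uV")
print(f"implicit t  : {m.implicit_time_ms:.2f} ms (valid={m.valid})")

series = simulate_flicker_series(WaveformParams(seed=42),
                                 FusionModel(cutoff_frequency=25.0), seed=42)
res = compute_fff(series)
print(f"FFF         : {res.fff_hz:.0f} Hz (contiguous; censored={res.censored})")
```

prints

```
irradiance  : 187.44 uW cm-2
baseline    : 0.02 uV
amplitude   : 182.63 uV
implicit t  : 106.13 ms (valid=True)
FFF         : 25 Hz (contiguous; censored=False)
```

The flash at log −1 attenuation of the 1874.4 μW cm⁻² source delivers
187.44 μW cm⁻²; the recovered b-wave amplitude (182.6 μV) is the noisy
estimate of the simulated peak, the implicit time falls inside the 50–230 ms
validity band, and the flicker sweep recovers the simulated 25 Hz fusion
cutoff exactly.

The same stages are available from the shell:

```bash
ergkit photometry ladder --source-intensity 1874.4
ergkit simulate flash --seed 3 --out-dir traces/
ergkit analyze bwave traces/*.txt --out metrics.tsv
ergkit simulate cohort --seed 2 --eyes 10 --out-dir cohort/
ergkit report cohort metrics.tsv --metric implicit_time_ms --out report.tsv
```

e.g. the ladder command prints the five-step intensity series
`0.18744, 1.8744, 18.744, 187.44, 1874.4` μW cm⁻².

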