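"""Flash-ERG b-wave quantification.

Given a corneal ERG trace, this module extracts:

* the baseline (mean of the first 50 ms, pre-stimulus),
* the b-wave amplitude (baseline-to-peak within a search window after light
  onset) as a proxy for ON-bipolar cell depolarization,
* the implicit time — time from light onset to b-wave onset — located by
  drawing the straight line through the 20% and 80% points of the final
  rising limb and intersecting it with the baseline level.

Implicit times below 50 ms or above 230 ms are flagged invalid and excluded
from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Inclusive implicit-time validity bounds, ms from light onset.
IMPLICIT_TIME_BOUNDS_MS = (50.0, 230.0)
#: Length of the pre-stimulus averaging window, ms.
BASELINE_WINDOW_MS = 50.0
#: Default b-wave peak search window length after light onset, ms.
SEARCH_WINDOW_MS = 300.0


class WaveformError(ValueError):
    """Base class for metric-extraction failures."""


class CrossingNotFoundError(WaveformError):
    """No upward crossing of the requested level before the peak."""


class DegenerateRiseError(WaveformError):
    """The 80% crossing does not follow the 20% crossing (t80 <= t20)."""


@dataclass
class ERGRecording:
    """One uniformly sampled ERG voltage trace with stimulus metadata.

    Time is implicit: sample ``i`` sits at ``i * 1000 / sampling_rate_hz`` ms,
    with the recording starting at t = 0 and the flash at ``stimulus_onset_ms``.
    """

    voltage_uV: np.ndarray
    sampling_rate_hz: float
    stimulus_onset_ms: float
    stimulus_duration_ms: float = 100.0
    irradiance_uW_cm2: float = float("nan")
    genotype: str = ""
    eye_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_uV, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("voltage must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage trace contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling rate must be positive")
        if self.stimulus_onset_ms < 0:
            raise ValueError("stimulus onset must be non-negative")
        self.voltage_uV = v

    @property
    def n_samples(self) -> int:
        return self.voltage_uV.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms


@dataclass
class BWaveMetrics:
    """b-wave metrics for one recording; invalid ones carry a reason."""

    baseline_uV: float
    amplitude_uV: float
    peak_time_ms: float
    t20_ms: float
    t80_ms: float
    implicit_time_ms: float
    valid: bool
    invalid_reason: Optional[str] = None


def compute_baseline(rec: ERGRecording, window_ms: float = BASELINE_WINDOW_MS) -> float:
    """Mean voltage over the first ``window_ms`` of the recording."""
    if window_ms <= 0:
        raise ValueError("baseline window must be positive")
    n = int(np.sum(rec.time_ms < window_ms))
    if n < 1:
        raise WaveformError("baseline window contains no samples")
    return float(np.mean(rec.voltage_uV[:n]))


def compute_b_wave_amplitude(
    rec: ERGRecording,
    baseline: float,
    search_window_ms: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Baseline-to-peak b-wave amplitude and peak time.

    The peak is the maximum voltage within the search window (default
    [onset, onset + 300 ms], clipped to the trace end); ties are broken by
    the earliest time.  The amplitude is measured from the baseline, not
    from the a-wave trough.
    """
    if search_window_ms is None:
        search_window_ms = (
            rec.stimulus_onset_ms,
            rec.stimulus_onset_ms + SEARCH_WINDOW_MS,
        )
    lo, hi = search_window_ms
    if lo < 0 or hi <= lo:
        raise ValueError("search window must be a positive-length interval")
    if lo >= rec.duration_ms:
        raise WaveformError("search window lies outside the recording")
    t = rec.time_ms
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise WaveformError("search window contains no samples")
    idx = np.flatnonzero(mask)
    seg = rec.voltage_uV[idx]
    peak_local = int(np.argmax(seg))  # argmax returns the first maximum
    peak_idx = idx[peak_local]
    return float(seg[peak_local] - baseline), float(t[peak_idx])


def find_fraction_crossing(
    rec: ERGRecording,
    baseline: float,
    amplitude: float,
    fraction: float,
    peak_time_ms: float,
) -> float:
    """Time of the last upward crossing of ``fraction * amplitude`` before the peak.

    The crossing is located by linear interpolation between the bracketing
    samples of the baseline-subtracted trace.  Selecting the *last* upward
    crossing picks the final rising limb into the peak, so the a-wave recovery
    limb can never be selected.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if amplitude <= 0:
        raise WaveformError("crossing search requires a positive amplitude")
    y = rec.voltage_uV - baseline
    target = fraction * amplitude
    peak_idx = int(round(peak_time_ms / rec.dt_ms))
    if not 0 < peak_idx < rec.n_samples:
        raise WaveformError("peak time lies outside the recording")
    a = y[:peak_idx]
    b = y[1 : peak_idx + 1]
    cross = np.flatnonzero((a < target) & (b >= target))
    if cross.size == 0:
        raise CrossingNotFoundError(
            f"no upward crossing of {fraction:.0%} level before the peak"
        )
    i = int(cross[-1])
    t = rec.time_ms
    frac = (target - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * rec.dt_ms)


def implicit_time_from_crossings(t20_ms: float, t80_ms: float, stimulus_onset_ms: float) -> float:
    """Implicit time from the 20/80 straight-line construction.

    The line through (t20, 0.2·A) and (t80, 0.8·A) on the baseline-subtracted
    curve intersects the baseline level at ``t20 − (t80 − t20)/3``; the
    implicit time is that intersection measured from light onset.
    """
    if t80_ms <= t20_ms:
        raise DegenerateRiseError("t80 must follow t20 (degenerate rise)")
    return t20_ms - (t80_ms - t20_ms) / 3.0 - stimulus_onset_ms


def classify_implicit_time(
    implicit_time_ms: float,
    bounds_ms: tuple[float, float] = IMPLICIT_TIME_BOUNDS_MS,
) -> tuple[bool, Optional[str]]:
    """Apply the validity filter: keep 50 <= IT <= 230 ms, flag the rest."""
    lo, hi = bounds_ms
    if implicit_time_ms < lo:
        return False, "below_filter"
    if implicit_time_ms > hi:
        return False, "above_filter"
    return True, None


def moving_average_denoise(rec: ERGRecording, smooth_ms: float) -> ERGRecording:
    """Centered moving-average smoothing over a ``smooth_ms`` window.

    Edge samples use the partial window (normalized), so the trace length and
    baseline window are unchanged.
    """
    if smooth_ms <= 0:
        raise ValueError("smoothing window must be positive")
    k = max(1, int(round(smooth_ms / rec.dt_ms)))
    if k == 1:
        return rec
    kernel = np.ones(k)
    smoothed = np.convolve(rec.voltage_uV, kernel, mode="same")
    norm = np.convolve(np.ones(rec.n_samples), kernel, mode="same")
    out = ERGRecording(
        voltage_uV=smoothed / norm,
        sampling_rate_hz=rec.sampling_rate_hz,
        stimulus_onset_ms=rec.stimulus_onset_ms,
        stimulus_duration_ms=rec.stimulus_duration_ms,
        irradiance_uW_cm2=rec.irradiance_uW_cm2,
        genotype=rec.genotype,
        eye_id=rec.eye_id,
        metadata=dict(rec.metadata, smoothed_ms=smooth_ms),
    )
    return out


def extract_b_wave_metrics(
    rec: ERGRecording,
    baseline_window_ms: float = BASELINE_WINDOW_MS,
    search_window_ms: Optional[tuple[float, float]] = None,
    search_length_ms: Optional[float] = None,
    bounds_ms: tuple[float, float] = IMPLICIT_TIME_BOUNDS_MS,
    smooth_ms: Optional[float] = None,
) -> BWaveMetrics:
    """Full b-wave metric chain for one recording.

    Runs baseline → amplitude/peak → 20%/80% crossings → implicit time →
    validity filter.  Failures that reflect the waveform (no crossing,
    non-positive amplitude, degenerate rise) yield an invalid result with a
    reason; configuration errors (bad windows) raise.  ``smooth_ms`` enables
    optional moving-average denoising before extraction (off by default).
    """
    nan = float("nan")
    if smooth_ms is not None:
        rec = moving_average_denoise(rec, smooth_ms)
    if search_window_ms is None and search_length_ms is not None:
        search_window_ms = (rec.stimulus_onset_ms,
                            rec.stimulus_onset_ms + search_length_ms)
    baseline = compute_baseline(rec, baseline_window_ms)
    amplitude, peak_time = compute_b_wave_amplitude(rec, baseline, search_window_ms)
    if amplitude <= 0:
        return BWaveMetrics(baseline, amplitude, peak_time, nan, nan, nan,
                            valid=False, invalid_reason="nonpositive_amplitude")
    try:
        t20 = find_fraction_crossing(rec, baseline, amplitude, 0.2, peak_time)
        t80 = find_fraction_crossing(rec, baseline, amplitude, 0.8, peak_time)
    except CrossingNotFoundError:
        return BWaveMetrics(baseline, amplitude, peak_time, nan, nan, nan,
                            valid=False, invalid_reason="no_crossing")
    try:
        it = implicit_time_from_crossings(t20, t80, rec.stimulus_onset_ms)
    except DegenerateRiseError:
        return BWaveMetrics(baseline, amplitude, peak_time, t20, t80, nan,
                            valid=False, invalid_reason="degenerate_rise")
    valid, reason = classify_implicit_time(it, bounds_ms)
    return BWaveMetrics(baseline, amplitude, peak_time, t20, t80, it,
                        valid=valid, invalid_reason=reason)


def metrics_table(
    recordings: Iterable[ERGRecording],
    **kwargs,
) -> pd.DataFrame:
    """Tidy per-recording metrics table with provenance columns.

    One row per recording: genotype, eye id, irradiance, stimulus attenuation
    (from metadata when present), all :class:`BWaveMetrics` fields, and the
    generator seed when available.
    """
    rows = []
    for rec in recordings:
        m = extract_b_wave_metrics(rec, **kwargs)
        rows.append(
            {
                "genotype": rec.genotype,
                "eye_id": rec.eye_id,
                "attenuation_log": rec.metadata.get("attenuation_log", float("nan")),
                "irradiance_uW_cm2": rec.irradiance_uW_cm2,
                "baseline_uV": m.baseline_uV,
                "amplitude_uV": m.amplitude_uV,
                "peak_time_ms": m.peak_time_ms,
                "t20_ms": m.t20_ms,
                "t80_ms": m.t80_ms,
                "implicit_time_ms": m.implicit_time_ms,
                "valid": m.valid,
                "invalid_reason": m.invalid_reason or "",
                "seed": rec.metadata.get("seed", ""),
            }
        )
    return pd.DataFrame(rows)
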