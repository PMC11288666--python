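"""Light-source photometry for ERG stimulation.

A white-light source is characterised by its spectral irradiance
(μW cm⁻² nm⁻¹ versus wavelength).  The stimulus intensity is the area under
that curve over the spectrometer band (189–800 nm), and the flash protocol
attenuates it in decadic log-unit steps (log −4 … log 0) with neutral-density
filtering assumed spectrally flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SPECTROMETER_BAND_NM = (189.0, 800.0)
DEFAULT_ATTENUATIONS = (-4.0, -3.0, -2.0, -1.0, 0.0)


@dataclass(frozen=True)
class SpectralIrradiance:
    """A measured (or simulated) source spectrum.

    Parameters
    ----------
    wavelength_nm : array
        Strictly ascending wavelengths, nm.
    irradiance : array
        Spectral irradiance per wavelength, μW cm⁻² nm⁻¹, non-negative.
    label : str
        Free-form source identifier.
    """

    wavelength_nm: np.ndarray
    irradiance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.irradiance, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise ValueError("wavelength and irradiance must be matching 1-D arrays")
        if w.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(v < 0):
            raise ValueError("spectral irradiance must be non-negative")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "irradiance", v)


@dataclass(frozen=True)
class IntensitySeries:
    """The log-attenuation stimulus ladder of one light source."""

    source_intensity: float          # μW cm⁻² at log 0
    attenuations: tuple[float, ...]  # log units, ascending, ≤ 0
    irradiances: tuple[float, ...]   # μW cm⁻² per step
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.attenuations) != len(self.irradiances):
            raise ValueError("attenuations and irradiances must align")
        if not np.all(np.diff(self.irradiances) > 0):
            raise ValueError("irradiances must increase with attenuation")


def integrate_spectrum(
    spectrum: SpectralIrradiance,
    lambda_min: float = SPECTROMETER_BAND_NM[0],
    lambda_max: float = SPECTROMETER_BAND_NM[1],
) -> float:
    """Source intensity as area under the spectral-irradiance curve.

    Trapezoidal integration on the native (possibly non-uniform) grid,
    restricted to ``[lambda_min, lambda_max]`` with linear interpolation at
    the clip boundaries.  Exact for piecewise-linear spectra.

    Returns
    -------
    float
        Integrated intensity, μW cm⁻².
    """
    if lambda_max <= lambda_min:
        raise ValueError("lambda_max must exceed lambda_min")
    w, v = spectrum.wavelength_nm, spectrum.irradiance
    lo = max(lambda_min, float(w[0]))
    hi = min(lambda_max, float(w[-1]))
    if lo >= hi:
        raise ValueError(
            f"integration band [{lambda_min}, {lambda_max}] nm does not overlap "
            f"the spectrum support [{w[0]}, {w[-1]}] nm"
        )
    inner = (w > lo) & (w < hi)
    ws = np.concatenate(([lo], w[inner], [hi]))
    vs = np.concatenate(
        ([np.interp(lo, w, v)], v[inner], [np.interp(hi, w, v)])
    )
    return float(np.trapezoid(vs, ws))


def attenuated_intensity(source_intensity: float, attenuation: float) -> float:
    """Irradiance after decadic attenuation by ``attenuation`` log units.

    ``attenuated_intensity(1874.4, -4)`` ≈ 0.19 μW cm⁻²; at log 0 the full
    source intensity is returned unchanged.
    """
    if source_intensity < 0:
        raise ValueError("source intensity must be non-negative")
    if attenuation > 0:
        raise ValueError("attenuation is expressed in log units <= 0")
    return source_intensity * 10.0 ** attenuation


def build_intensity_series(
    source_intensity: float,
    attenuations: Sequence[float] = DEFAULT_ATTENUATIONS,
    label: str = "",
) -> IntensitySeries:
    """Build the stimulus ladder for one source (default log −4 … log 0)."""
    atts = tuple(float(a) for a in attenuations)
    if not atts:
        raise ValueError("attenuation list must not be empty")
    if not all(a <= 0 for a in atts):
        raise ValueError("attenuations must be <= 0 log units")
    if not all(b > a for a, b in zip(atts, atts[1:])):
        raise ValueError("attenuations must be strictly ascending")
    irr = tuple(attenuated_intensity(source_intensity, a) for a in atts)
    return IntensitySeries(
        source_intensity=float(source_intensity),
        attenuations=atts,
        irradiances=irr,
        label=label,
    )
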