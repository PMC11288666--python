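"""File formats, run configuration, and logging.

Trace dialect: comment-prefixed ``# key: value`` metadata header lines
followed by a two-column delimited table (``time_ms``, ``voltage_uV``).
Spectra use two columns (``wavelength_nm``, ``spectral_irradiance_uW_cm2_nm``).
Floats are written with 9 significant digits so repeated writes are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .photometry import DEFAULT_ATTENUATIONS, SpectralIrradiance
from .waveform import ERGRecording

logger = logging.getLogger("ergkit")

FLOAT_FMT = "%.9g"
#: Relative tolerance for the uniform-grid check on read.
GRID_RTOL = 1e-6

_HEADER_FLOAT_KEYS = {
    "sampling_rate_hz", "stimulus_onset_ms", "stimulus_duration_ms",
    "irradiance_uW_cm2",
}
_HEADER_STR_KEYS = {"genotype", "eye_id", "seed"}


@dataclass
class RunConfig:
    """Resolved pipeline configuration; fully YAML-serializable.

    Defaults mirror the study protocol: 1 kHz sampling, flash onset 100 ms
    into a 1 s trace, 100 ms flashes over log −4…0 attenuation of a
    1874.4 μW cm⁻² source, flicker sweeps 7→40 Hz in 1 Hz steps with 15 ms
    pulses and 2 s records analysed over 0–50 Hz.
    """

    sampling_rate_hz: float = 1000.0
    stimulus_onset_ms: float = 100.0
    trace_duration_ms: float = 1000.0
    stimulus_duration_ms: float = 100.0
    attenuations: tuple[float, ...] = DEFAULT_ATTENUATIONS
    source_intensity: float = 1874.4
    flicker_start_hz: float = 7.0
    flicker_step_hz: float = 1.0
    flicker_max_hz: float = 40.0
    flicker_pulse_ms: float = 15.0
    flicker_duration_ms: float = 2000.0
    band_max_hz: float = 50.0
    theta: float = 5.0
    exclusion_radius_bins: int = 1
    fff_mode: str = "contiguous"
    baseline_window_ms: float = 50.0
    search_window_ms: float = 300.0
    implicit_time_bounds_ms: tuple[float, float] = (50.0, 230.0)
    test_variant: str = "student"
    reference_genotype: str = "WT"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("attenuations", "implicit_time_bounds_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        d["attenuations"] = list(d["attenuations"])
        d["implicit_time_bounds_ms"] = list(d["implicit_time_bounds_ms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        d = asdict(self)
        payload = json.dumps(d, sort_keys=True, default=list).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_trace(rec: ERGRecording, path: Union[str, Path]) -> None:
    """Write one recording in the text trace dialect."""
    path = Path(path)
    lines = [
        f"# sampling_rate_hz: {_fmt(rec.sampling_rate_hz)}",
        f"# stimulus_onset_ms: {_fmt(rec.stimulus_onset_ms)}",
        f"# stimulus_duration_ms: {_fmt(rec.stimulus_duration_ms)}",
        f"# irradiance_uW_cm2: {_fmt(rec.irradiance_uW_cm2)}",
        f"# genotype: {rec.genotype}",
        f"# eye_id: {rec.eye_id}",
        f"# seed: {rec.metadata.get('seed', '')}",
        "time_ms\tvoltage_uV",
    ]
    t = rec.time_ms
    for ti, vi in zip(t, rec.voltage_uV):
        lines.append(f"{_fmt(ti)}\t{_fmt(vi)}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: Union[str, Path], config: Optional[RunConfig] = None) -> ERGRecording:
    """Read a trace file, validating the uniform time grid.

    Metadata keys missing from the header are filled from ``config`` (when
    given) with a logged warning.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
            continue
        if line.startswith("time_ms"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row") from exc
    if len(rows) < 2:
        raise ValueError(f"{path}: trace needs at least two samples")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    dt = np.diff(t)
    if np.any(dt <= 0) or (np.max(dt) - np.min(dt)) > GRID_RTOL * np.mean(dt):
        raise ValueError(f"{path}: non-uniform time grid")

    def _get_float(key: str, fallback: Optional[float]) -> float:
        if key in header and header[key] != "":
            return float(header[key])
        if fallback is None:
            raise ValueError(f"{path}: missing required header key {key!r}")
        logger.warning("%s: header key %r missing; using config value %s",
                       path.name, key, fallback)
        return float(fallback)

    fs_grid = 1000.0 / float(np.mean(dt))
    cfg = config or None
    fs = float(header.get("sampling_rate_hz", fs_grid))
    onset = _get_float("stimulus_onset_ms",
                       cfg.stimulus_onset_ms if cfg else None)
    duration = _get_float("stimulus_duration_ms",
                          cfg.stimulus_duration_ms if cfg else 100.0)
    irr = float(header["irradiance_uW_cm2"]) if header.get("irradiance_uW_cm2") else (
        _get_float("irradiance_uW_cm2", cfg.source_intensity) if cfg else float("nan")
    )
    metadata: dict = {"source_file": str(path)}
    if header.get("seed"):
        metadata["seed"] = int(float(header["seed"]))
    return ERGRecording(
        voltage_uV=v,
        sampling_rate_hz=fs,
        stimulus_onset_ms=onset,
        stimulus_duration_ms=duration,
        irradiance_uW_cm2=irr,
        genotype=header.get("genotype", ""),
        eye_id=header.get("eye_id", ""),
        metadata=metadata,
    )


def write_spectrum(spec: SpectralIrradiance, path: Union[str, Path]) -> None:
    path = Path(path)
    lines = [f"# label: {spec.label}", "wavelength_nm\tspectral_irradiance_uW_cm2_nm"]
    for w, v in zip(spec.wavelength_nm, spec.irradiance):
        lines.append(f"{_fmt(w)}\t{_fmt(v)}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: Union[str, Path]) -> SpectralIrradiance:
    path = Path(path)
    label = ""
    ws, vs = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("wavelength_nm"):
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("label:"):
                label = body.split(":", 1)[1].strip()
            continue
        a, b = line.split()
        ws.append(float(a))
        vs.append(float(b))
    return SpectralIrradiance(np.array(ws), np.array(vs), label=label)


def write_metrics(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a metrics table as deterministic tab-separated text.

    Column order is preserved, floats use 9 significant digits, and the line
    terminator is fixed, so writing the same records twice produces
    byte-identical files.
    """
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
                   lineterminator="\n")


def read_metrics(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def log_stage(stage: str, seed, config: Optional[RunConfig] = None,
              input_hash: str = "") -> None:
    """One structured log line per pipeline stage."""
    logger.info("stage=%s seed=%s config=%s input=%s", stage, seed,
                config.config_hash() if config else "-", input_hash or "-")
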