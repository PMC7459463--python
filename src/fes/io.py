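"""Plain-text readers and writers, run configuration, and the pipeline driver.

All formats are diffable text: CSV for numeric arrays (time series, spectra)
and JSON for structured records (fingerprints, spectrum models, libraries,
run summaries).  Writers are deterministic — stable key order, fixed numeric
formatting at 12 significant digits — so identical inputs give byte-identical
files, and every reader/writer pair round-trips valid objects exactly to
that precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import fingerprint as fp
from . import simulate, spectral
from .classify import FingerprintLibrary, bit_agreement
from .errors import ParseError, PipelineError, ValidationError
from .types import (
    BandPlan,
    Fingerprint,
    PowerSpectrum,
    SpectrumModel,
    TimeSeriesRecord,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_spectrum",
    "write_spectrum",
    "read_fingerprint",
    "write_fingerprint",
    "read_model",
    "write_model",
    "read_library",
    "write_library",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("fes")

_FLOAT_FMT = "{:.12e}"  # 13 significant digits; round-trips to 12 safely


def _parse_numeric_rows(path: Union[str, Path]) -> Tuple[List[List[float]], int]:
    """Parse a 1- or 2-column delimited text file into float rows.

    Auto-detects an optional header row and comma/tab/whitespace delimiters.
    Returns (rows, n_columns). Errors name the offending line number.
    """
    path = Path(path)
    rows: List[List[float]] = []
    n_cols: Optional[int] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = [p for p in text.replace(",", " ").replace("\t", " ").split() if p]
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header row
                raise ParseError(f"{path}:{lineno}: non-numeric row: {text!r}")
            if n_cols is None:
                n_cols = len(values)
                if n_cols not in (1, 2):
                    raise ParseError(
                        f"{path}:{lineno}: expected 1 or 2 columns, found {n_cols}"
                    )
            elif len(values) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no numeric data found")
    return rows, n_cols or 1


def read_timeseries(
    path: Union[str, Path],
    sampling_rate_hint: Optional[float] = None,
    label: str = "",
) -> TimeSeriesRecord:
    """Read a noise record from delimited text.

    One column (value): the sampling rate must be supplied via
    ``sampling_rate_hint``. Two columns (time_s, value): the time grid must
    be uniform to 1e-6 relative tolerance and determines the sampling rate.
    """
    path = Path(path)
    rows, n_cols = _parse_numeric_rows(path)
    data = np.asarray(rows, dtype=float)
    if n_cols == 1:
        if sampling_rate_hint is None:
            raise ParseError(
                f"{path}: one-column file needs an explicit sampling rate "
                f"(pass sampling_rate_hint / --fs)"
            )
        return TimeSeriesRecord(
            samples=data[:, 0], sampling_rate=sampling_rate_hint,
            label=label or path.stem,
        )
    times, values = data[:, 0], data[:, 1]
    dt = np.diff(times)
    if len(dt) < 1 or np.any(dt <= 0):
        raise ParseError(f"{path}: time column must be strictly increasing")
    dt0 = float(np.median(dt))
    if np.any(np.abs(dt - dt0) > 1e-6 * dt0):
        bad = int(np.argmax(np.abs(dt - dt0) > 1e-6 * dt0)) + 2
        raise ParseError(
            f"{path}: non-uniform time grid near data row {bad} "
            f"(step {dt[bad - 2]:g} s vs median {dt0:g} s)"
        )
    fs = 1.0 / dt0
    if sampling_rate_hint is not None and not np.isclose(
        fs, sampling_rate_hint, rtol=1e-6
    ):
        raise ParseError(
            f"{path}: time column implies {fs:g} Hz but sampling_rate_hint "
            f"is {sampling_rate_hint:g} Hz"
        )
    return TimeSeriesRecord(samples=values, sampling_rate=fs, label=label or path.stem)


def write_timeseries(ts: TimeSeriesRecord, path: Union[str, Path]) -> None:
    """Write a record as two-column CSV (time_s, value)."""
    path = Path(path)
    t = np.arange(len(ts)) / ts.sampling_rate
    with path.open("w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, ts.samples):
            fh.write(f"{_FLOAT_FMT.format(ti)},{_FLOAT_FMT.format(vi)}\n")


def read_spectrum(path: Union[str, Path], label: str = "") -> PowerSpectrum:
    """Read a spectrum CSV with columns (frequency_hz, psd)."""
    path = Path(path)
    rows, n_cols = _parse_numeric_rows(path)
    if n_cols != 2:
        raise ParseError(f"{path}: spectrum files need 2 columns (frequency_hz, psd)")
    data = np.asarray(rows, dtype=float)
    for i, (f, s) in enumerate(data, start=1):
        if s <= 0:
            raise ParseError(
                f"{path}: data row {i}: density must be > 0, got {s:g} at {f:g} Hz"
            )
    try:
        return PowerSpectrum(
            frequencies=data[:, 0], density=data[:, 1], label=label or path.stem
        )
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_spectrum(ps: PowerSpectrum, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("frequency_hz,psd\n")
        for f, s in zip(ps.frequencies, ps.density):
            fh.write(f"{_FLOAT_FMT.format(f)},{_FLOAT_FMT.format(s)}\n")


def _fingerprint_to_dict(f: Fingerprint) -> Dict:
    return {
        "scheme": f.scheme,
        "bits": list(f.bits),
        "band": {
            "f_low_hz": f.plan.f_low,
            "f_high_hz": f.plan.f_high,
            "n_subbands": f.plan.n_subbands,
            "edges_hz": [float(e) for e in f.plan.edges],
        },
        "tie_tolerance": f.tie_tolerance,
        "reference_label": f.reference_label,
        "label": f.label,
    }


def _fingerprint_from_dict(d: Dict, where: str) -> Fingerprint:
    try:
        band = d["band"]
        plan = BandPlan(
            f_low=band["f_low_hz"],
            f_high=band["f_high_hz"],
            n_subbands=band["n_subbands"],
            edges=np.asarray(band["edges_hz"], dtype=float),
        )
        return Fingerprint(
            bits=tuple(d["bits"]),
            scheme=d["scheme"],
            plan=plan,
            tie_tolerance=d.get("tie_tolerance", 0.0),
            reference_label=d.get("reference_label"),
            label=d.get("label", ""),
        )
    except KeyError as e:
        raise ParseError(f"{where}: missing field {e}") from e
    except ValidationError as e:
        raise ParseError(f"{where}: {e}") from e


def read_fingerprint(path: Union[str, Path]) -> Fingerprint:
    path = Path(path)
    with path.open() as fh:
        d = json.load(fh)
    return _fingerprint_from_dict(d, str(path))


def write_fingerprint(f: Fingerprint, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        json.dump(_fingerprint_to_dict(f), fh, indent=2)
        fh.write("\n")


def read_model(path: Union[str, Path]) -> SpectrumModel:
    """Read a piecewise power-law spectrum model from JSON.

    Expected fields: ``segments`` — list of ``[f_lo_hz, f_hi_hz, exponent]``
    triples — ``overall_level`` and optional ``label``.
    """
    path = Path(path)
    with path.open() as fh:
        d = json.load(fh)
    try:
        return SpectrumModel(
            segments=tuple(tuple(seg) for seg in d["segments"]),
            overall_level=d.get("overall_level", 1.0),
            label=d.get("label", path.stem),
        )
    except (KeyError, TypeError, ValidationError) as e:
        raise ParseError(f"{path}: invalid model file: {e}") from e


def write_model(model: SpectrumModel, path: Union[str, Path]) -> None:
    d = {
        "segments": [list(seg) for seg in model.segments],
        "overall_level": model.overall_level,
        "label": model.label,
    }
    with Path(path).open("w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


def read_library(path: Union[str, Path]) -> FingerprintLibrary:
    """Read a labelled fingerprint library from JSON ({"entries": {label: fp}})."""
    path = Path(path)
    with path.open() as fh:
        d = json.load(fh)
    if "entries" not in d or not isinstance(d["entries"], dict):
        raise ParseError(f"{path}: library file needs an 'entries' mapping")
    entries = {
        label: _fingerprint_from_dict(fd, f"{path} entry {label!r}")
        for label, fd in d["entries"].items()
    }
    try:
        return FingerprintLibrary(entries)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_library(library: FingerprintLibrary, path: Union[str, Path]) -> None:
    d = {
        "entries": {
            label: _fingerprint_to_dict(f)
            for label, f in sorted(library.entries.items())
        }
    }
    with Path(path).open("w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for an end-to-end pipeline run.

    Acquisition and analysis parameters are explicit here and logged on
    every run, so no setting is ever implicit in the output.
    """

    n_samples: int = 2**18
    sampling_rate: float = 1000.0
    segment_length: int = spectral.DEFAULT_SEGMENT_LENGTH
    overlap_fraction: float = spectral.DEFAULT_OVERLAP
    window_name: str = spectral.DEFAULT_WINDOW
    log_bins_per_decade: int = spectral.DEFAULT_BINS_PER_DECADE
    f_low: Optional[float] = None  # None -> default "meaningful" band
    f_high: Optional[float] = None
    n_subbands: int = fp.DEFAULT_N_SUBBANDS
    tie_tolerance: float = fp.DEFAULT_TIE_TOLERANCE
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 2 * self.segment_length:
            raise ValidationError(
                "n_samples: record must cover at least two Welch segments"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate: must be > 0")
        if not 0 <= self.overlap_fraction < 1:
            raise ValidationError("overlap_fraction: must be in [0, 1)")
        if self.log_bins_per_decade < 1:
            raise ValidationError("log_bins_per_decade: must be >= 1")
        if (self.f_low is None) != (self.f_high is None):
            raise ValidationError("f_low/f_high: give both band edges or neither")
        if self.f_low is not None and not 0 < self.f_low < self.f_high:
            raise ValidationError("f_low/f_high: need 0 < f_low < f_high")
        if self.n_subbands < 1:
            raise ValidationError("n_subbands: must be >= 1")
        if self.tie_tolerance < 0:
            raise ValidationError("tie_tolerance: must be >= 0")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        with Path(path).open() as fh:
            d = json.load(fh)
        try:
            return cls(**d)
        except TypeError as e:
            raise ParseError(f"{path}: {e}") from e


def _analysis_spectrum(ts: TimeSeriesRecord, config: RunConfig) -> PowerSpectrum:
    """time series -> Welch PSD -> log binning -> band selection."""
    ps = spectral.estimate_psd(
        ts, config.segment_length, config.overlap_fraction, config.window_name
    )
    ps = spectral.log_bin_spectrum(ps, config.log_bins_per_decade)
    if config.f_low is not None:
        band = (config.f_low, config.f_high)
    else:
        band = spectral.default_band(ps, nyquist=ts.sampling_rate / 2)
    return spectral.select_band(ps, *band)


def run_pipeline(
    config: RunConfig,
    agent_model: SpectrumModel,
    reference_model: SpectrumModel,
    out_dir: Union[str, Path],
) -> Dict:
    """Simulate a measurement pair and fingerprint it against a reference.

    Runs the full chain — simulate-pair -> PSD x2 -> binary and ternary
    fingerprints x2 -> bit agreement — writing every artifact (spectra,
    fingerprints, summary) under ``out_dir`` and returning the summary dict.
    The summary embeds the fully resolved configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", asdict(config))

    stage = "simulate"
    try:
        m1, m2 = simulate.simulate_measurement_pair(
            agent_model, config.n_samples, config.sampling_rate, config.seed
        )
        stage = "psd"
        ps1 = _analysis_spectrum(m1, config)
        ps2 = _analysis_spectrum(m2, config)
        write_spectrum(ps1, out / "spectrum_m1.csv")
        write_spectrum(ps2, out / "spectrum_m2.csv")

        stage = "fingerprint"
        plan = fp.make_band_plan(ps1.f_min, ps1.f_max, config.n_subbands)
        ref_ps = simulate.model_psd(
            reference_model, np.geomspace(plan.f_low, plan.f_high, 256)
        )
        fps = {}
        for name, ps in (("m1", ps1), ("m2", ps2)):
            b = fp.binary_fingerprint(ps, plan)
            t = fp.ternary_fingerprint(ps, ref_ps, plan, config.tie_tolerance)
            write_fingerprint(b, out / f"binary_{name}.json")
            write_fingerprint(t, out / f"ternary_{name}.json")
            fps[name] = (b, t)

        stage = "compare"
        summary = {
            "config": asdict(config),
            "agent_model": agent_model.label,
            "reference_model": reference_model.label,
            "band_hz": [plan.f_low, plan.f_high],
            "binary_bits": {n: list(v[0].bits) for n, v in fps.items()},
            "ternary_bits": {n: list(v[1].bits) for n, v in fps.items()},
            "binary_agreement": bit_agreement(fps["m1"][0], fps["m2"][0]),
            "ternary_agreement": bit_agreement(fps["m1"][1], fps["m2"][1]),
        }
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False)
        fh.write("\n")
    logger.info(
        "pipeline done: binary agreement %.3f, ternary agreement %.3f",
        summary["binary_agreement"], summary["ternary_agreement"],
    )
    return summary
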