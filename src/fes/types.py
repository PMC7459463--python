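"""Core domain types.

The pipeline moves data through four containers:

``TimeSeriesRecord``
    A sampled sensor-noise voltage trace with its sampling rate.
``PowerSpectrum``
    A one-sided power density estimate on an ascending positive frequency
    grid (the "PDS" of fluctuation-enhanced sensing).
``BandPlan``
    An analysis band ``[f_low, f_high]`` tiled into contiguous sub-bands of
    equal width in ``log10(f)``.
``Fingerprint``
    The ordered symbol string extracted from the spectrum's slope structure,
    over the alphabet ``{-1, +1}`` (binary scheme) or ``{-1, 0, +1}``
    (ternary scheme, relative to a reference odor).

All containers validate their invariants at construction and are immutable;
array fields are stored as read-only ``numpy`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "TimeSeriesRecord",
    "PowerSpectrum",
    "BandPlan",
    "SlopeProfile",
    "Fingerprint",
    "SpectrumModel",
]

BINARY = "binary"
TERNARY = "ternary"
SCHEMES = (BINARY, TERNARY)


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float, copy=True)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class TimeSeriesRecord:
    """A sampled sensor-noise voltage trace.

    Parameters
    ----------
    samples : array-like of float
        Voltage samples (arbitrary units). Must all be finite.
    sampling_rate : float
        Sampling rate in Hz, strictly positive and finite.
    label : str, optional
        Free-text provenance (agent / sensor / measurement id).
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = _readonly(np.atleast_1d(self.samples))
        if samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValidationError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values")
        fs = float(self.sampling_rate)
        if not np.isfinite(fs) or fs <= 0:
            raise ValidationError(
                f"sampling_rate must be positive and finite, got {self.sampling_rate!r}"
            )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sampling_rate", fs)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0


@dataclass(frozen=True)
class PowerSpectrum:
    """A one-sided power density spectrum on positive frequencies.

    Frequencies are strictly ascending and exclude DC; densities are strictly
    positive (log-log slope analysis is undefined otherwise — spectra with
    non-positive densities are rejected, never silently floored).
    """

    frequencies: np.ndarray
    density: np.ndarray
    n_averages: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        f = _readonly(np.atleast_1d(self.frequencies))
        s = _readonly(np.atleast_1d(self.density))
        if f.shape != s.shape or f.ndim != 1:
            raise ValidationError("frequencies and density must be 1-D of equal length")
        if f.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(s)):
            raise ValidationError("spectrum contains non-finite values")
        if f[0] <= 0:
            raise ValidationError("frequencies must be strictly positive (DC excluded)")
        if not np.all(np.diff(f) > 0):
            raise ValidationError("frequencies must be strictly ascending")
        if np.any(s <= 0):
            bad = int(np.argmax(s <= 0))
            raise ValidationError(
                f"density must be strictly positive; first offending point at "
                f"index {bad} (f={f[bad]:g} Hz, value {s[bad]:g})"
            )
        if int(self.n_averages) < 1:
            raise ValidationError("n_averages must be >= 1")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "density", s)
        object.__setattr__(self, "n_averages", int(self.n_averages))

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])


@dataclass(frozen=True)
class BandPlan:
    """An analysis band tiled into ``n_subbands`` log-equal sub-bands.

    ``edges`` has length ``n_subbands + 1``, runs from ``f_low`` to
    ``f_high``, and is equally spaced in ``log10(f)`` — a contiguous tiling
    with no gaps or overlaps. Use :func:`fes.fingerprint.make_band_plan` to
    construct one.
    """

    f_low: float
    f_high: float
    n_subbands: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        f_low, f_high = float(self.f_low), float(self.f_high)
        n = int(self.n_subbands)
        if not (0 < f_low < f_high) or not np.isfinite(f_high):
            raise ValidationError(
                f"need 0 < f_low < f_high, got f_low={self.f_low!r}, f_high={self.f_high!r}"
            )
        if n < 1:
            raise ValidationError("n_subbands must be >= 1")
        edges = _readonly(np.atleast_1d(self.edges))
        if edges.size != n + 1:
            raise ValidationError("edges must have length n_subbands + 1")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("edges must be strictly ascending")
        if not (np.isclose(edges[0], f_low) and np.isclose(edges[-1], f_high)):
            raise ValidationError("edges must span exactly [f_low, f_high]")
        log_steps = np.diff(np.log10(edges))
        if not np.allclose(log_steps, log_steps[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("edges must be equally spaced in log10(f)")
        object.__setattr__(self, "f_low", f_low)
        object.__setattr__(self, "f_high", f_high)
        object.__setattr__(self, "n_subbands", n)
        object.__setattr__(self, "edges", edges)

    def subband(self, i: int) -> Tuple[float, float]:
        """Return the ``(f_lo, f_hi)`` edges of sub-band ``i``."""
        if not 0 <= i < self.n_subbands:
            raise ValidationError(f"sub-band index {i} out of range")
        return float(self.edges[i]), float(self.edges[i + 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandPlan):
            return NotImplemented
        return self.n_subbands == other.n_subbands and np.allclose(
            self.edges, other.edges, rtol=1e-12
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.n_subbands, round(self.f_low, 12), round(self.f_high, 12)))


@dataclass(frozen=True)
class SlopeProfile:
    """Global and per-sub-band chord slopes of a log-log spectrum."""

    global_slope: float
    local_slopes: np.ndarray
    plan: BandPlan

    def __post_init__(self) -> None:
        ls = _readonly(np.atleast_1d(self.local_slopes))
        if ls.size != self.plan.n_subbands:
            raise ValidationError("need one local slope per sub-band")
        if not np.isfinite(self.global_slope) or not np.all(np.isfinite(ls)):
            raise ValidationError("slopes must be finite")
        object.__setattr__(self, "global_slope", float(self.global_slope))
        object.__setattr__(self, "local_slopes", ls)


@dataclass(frozen=True)
class Fingerprint:
    """An ordered symbol string over ``{-1, 0, +1}``.

    ``scheme='binary'`` uses only ``{-1, +1}`` and carries no reference;
    ``scheme='ternary'`` is computed relative to a reference-odor spectrum
    whose identity is recorded in ``reference_label``, with ``0`` meaning the
    agent's and reference's local slopes agree within ``tie_tolerance``.
    """

    bits: Tuple[int, ...]
    scheme: str
    plan: BandPlan
    tie_tolerance: float = 0.0
    reference_label: Optional[str] = None
    label: str = ""

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        allowed = {-1, 1} if self.scheme == BINARY else {-1, 0, 1}
        if not set(bits) <= allowed:
            raise ValidationError(
                f"{self.scheme} fingerprint bits must be in {sorted(allowed)}, got {bits}"
            )
        if len(bits) != self.plan.n_subbands:
            raise ValidationError("fingerprint length must equal the plan's n_subbands")
        if float(self.tie_tolerance) < 0:
            raise ValidationError("tie_tolerance must be >= 0")
        if self.scheme == BINARY and self.reference_label is not None:
            raise ValidationError("binary fingerprints carry no reference_label")
        if self.scheme == TERNARY and self.reference_label is None:
            raise ValidationError("ternary fingerprints require a reference_label")
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "tie_tolerance", float(self.tie_tolerance))

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class SpectrumModel:
    """Piecewise power-law PSD model, the simulator's analytic ground truth.

    ``segments`` is an ascending, contiguous list of ``(f_lo, f_hi, gamma)``
    triples: on segment *i* the density follows ``c_i * f**(-gamma_i)``. The
    amplitudes ``c_i`` are chained so the density is continuous across segment
    boundaries, anchored by ``overall_level`` = density at the first
    segment's ``f_lo``.
    """

    segments: Tuple[Tuple[float, float, float], ...]
    overall_level: float = 1.0
    label: str = ""
    # derived, set in __post_init__
    _amplitudes: Tuple[float, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        segs = tuple(
            (float(lo), float(hi), float(g)) for lo, hi, g in self.segments
        )
        if not segs:
            raise ValidationError("model needs at least one segment")
        level = float(self.overall_level)
        if not np.isfinite(level) or level <= 0:
            raise ValidationError("overall_level must be positive and finite")
        for lo, hi, g in segs:
            if not (0 < lo < hi) or not np.isfinite(hi) or not np.isfinite(g):
                raise ValidationError(f"invalid segment ({lo}, {hi}, {g})")
        for (lo1, hi1, _), (lo2, _, _) in zip(segs, segs[1:]):
            if not np.isclose(hi1, lo2, rtol=1e-12):
                raise ValidationError(
                    f"segments must be contiguous; gap between {hi1} and {lo2} Hz"
                )
        # chain amplitudes for continuity: c0 anchored by overall_level at f_lo0,
        # then c_{i+1} = c_i * f_b ** (g_{i+1} - g_i) at each boundary f_b
        amps = [level * segs[0][0] ** segs[0][2]]
        for (lo1, hi1, g1), (_, _, g2) in zip(segs, segs[1:]):
            amps.append(amps[-1] * hi1 ** (g2 - g1))
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "overall_level", level)
        object.__setattr__(self, "_amplitudes", tuple(amps))

    @property
    def f_min(self) -> float:
        return self.segments[0][0]

    @property
    def f_max(self) -> float:
        return self.segments[-1][1]

    @property
    def exponents(self) -> Tuple[float, ...]:
        return tuple(g for _, _, g in self.segments)
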