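"""Spectral-slope fingerprints.

A fluctuation-enhanced-sensing fingerprint encodes the *shape* of a noise
power density spectrum as a short symbol string.  On a log-log plot the
analysis band ``[f_low, f_high]`` gets a single *global* chord slope — the
straight line connecting the band's two endpoints — and is tiled into
log-equal sub-bands, each with its own *local* chord slope.

Binary scheme
    ``bit_i = -1`` where the local slope is below the global slope, ``+1``
    otherwise (ties go to +1). The alphabet is ``{-1, +1}``.

Ternary scheme
    Each local slope is compared with the local slope of a *reference odor*
    spectrum over the same sub-band: ``-1`` if smaller, ``+1`` if greater,
    ``0`` if equal within ``tie_tolerance``. The alphabet ``{-1, 0, +1}``
    carries ``log2(3) ~ 1.585`` bits per symbol, an increase of
    ``100*(log2 3 - 1) ~ 58.5 %`` over a binary bit, and the reference makes
    the code relative: different references yield different fingerprints of
    the same agent.

Chord slopes deliberately ignore interior points — no least-squares fit —
and are invariant under any positive rescaling of the density, so the
fingerprint responds only to spectral shape, never to signal amplitude.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .errors import (
    AlignmentError,
    BandError,
    ExtrapolationError,
    ValidationError,
)
from .spectral import resample_to_grid, select_band
from .types import BINARY, TERNARY, BandPlan, Fingerprint, PowerSpectrum, SlopeProfile

__all__ = [
    "endpoint_slope",
    "make_band_plan",
    "slope_profile",
    "binary_fingerprint",
    "ternary_fingerprint",
    "alphabet_entropy",
    "entropy_increase",
    "least_squares_slope",
    "DEFAULT_N_SUBBANDS",
    "DEFAULT_TIE_TOLERANCE",
]

DEFAULT_N_SUBBANDS = 5
DEFAULT_TIE_TOLERANCE = 0.05


def _log_value_at(ps: PowerSpectrum, f: float) -> float:
    """log10 density at frequency f, by log-log interpolation (no extrapolation)."""
    rtol = 1e-12
    if f < ps.f_min * (1 - rtol) or f > ps.f_max * (1 + rtol):
        raise ExtrapolationError(
            f"frequency {f:g} Hz outside the spectrum support "
            f"[{ps.f_min:g}, {ps.f_max:g}] Hz"
        )
    f = min(max(f, ps.f_min), ps.f_max)
    return float(
        np.interp(np.log10(f), np.log10(ps.frequencies), np.log10(ps.density))
    )


def endpoint_slope(ps: PowerSpectrum, f_lo: float, f_hi: float) -> float:
    """Chord slope of the log-log spectrum between two frequencies.

    Returns ``(log10 S(f_hi) - log10 S(f_lo)) / (log10 f_hi - log10 f_lo)``.
    Endpoint densities are obtained by log-log interpolation when the
    frequencies are not on-grid; interior points are ignored by construction.
    """
    if not (0 < f_lo < f_hi):
        raise ValidationError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    return (_log_value_at(ps, f_hi) - _log_value_at(ps, f_lo)) / (
        math.log10(f_hi) - math.log10(f_lo)
    )


def least_squares_slope(ps: PowerSpectrum, f_lo: float, f_hi: float) -> float:
    """Least-squares log-log slope over a band (non-default alternative).

    Provided for comparison only; the fingerprint operations use
    :func:`endpoint_slope` (the chord), which is the method's convention.
    """
    band = select_band(ps, f_lo, f_hi)
    x = np.log10(band.frequencies)
    y = np.log10(band.density)
    return float(np.polyfit(x, y, 1)[0])


def make_band_plan(
    f_low: float, f_high: float, n_subbands: int = DEFAULT_N_SUBBANDS
) -> BandPlan:
    """Tile ``[f_low, f_high]`` into ``n_subbands`` log-equal sub-bands.

    Edge ``k`` sits at ``f_low * (f_high/f_low)**(k/n)``, so consecutive
    edges share one ratio and the tiling is contiguous in log frequency.
    """
    if not (0 < f_low < f_high):
        raise ValidationError(f"need 0 < f_low < f_high, got ({f_low}, {f_high})")
    n = int(n_subbands)
    if n < 1:
        raise ValidationError("n_subbands must be >= 1")
    edges = np.geomspace(f_low, f_high, n + 1)
    return BandPlan(f_low=f_low, f_high=f_high, n_subbands=n, edges=edges)


def slope_profile(ps: PowerSpectrum, plan: BandPlan) -> SlopeProfile:
    """Global and per-sub-band chord slopes over a band plan.

    For log-equal plans the local slopes telescope: their mean equals the
    global slope exactly, because interior endpoint values cancel in the sum.
    """
    g = endpoint_slope(ps, plan.f_low, plan.f_high)
    locs = np.array(
        [endpoint_slope(ps, *plan.subband(i)) for i in range(plan.n_subbands)]
    )
    return SlopeProfile(global_slope=g, local_slopes=locs, plan=plan)


def binary_fingerprint(ps: PowerSpectrum, plan: BandPlan) -> Fingerprint:
    """Binary fingerprint: local slope below the global slope -> -1, else +1.

    The tie case (local equals global, e.g. on a pure power law) takes +1.
    """
    prof = slope_profile(ps, plan)
    bits = tuple(
        -1 if loc < prof.global_slope else 1 for loc in prof.local_slopes
    )
    return Fingerprint(bits=bits, scheme=BINARY, plan=plan, label=ps.label)


def ternary_fingerprint(
    agent: PowerSpectrum,
    reference: PowerSpectrum,
    plan: BandPlan,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> Fingerprint:
    """Ternary fingerprint of an agent spectrum relative to a reference odor.

    For each sub-band, with ``d = agent_local_slope - reference_local_slope``:
    ``0`` if ``|d| <= tie_tolerance``, else ``sign(d)``.

    The reference is first resampled onto the agent's in-band grid in log-log
    space so both slope profiles share identical sub-band endpoints; both
    spectra must therefore cover the plan's full band.
    """
    if tie_tolerance < 0:
        raise ValidationError("tie_tolerance must be >= 0")
    for name, ps in (("agent", agent), ("reference", reference)):
        rtol = 1e-12
        if ps.f_min > plan.f_low * (1 + rtol) or ps.f_max < plan.f_high * (1 - rtol):
            raise AlignmentError(
                f"{name} spectrum supported on [{ps.f_min:g}, {ps.f_max:g}] Hz "
                f"does not cover the analysis band [{plan.f_low:g}, {plan.f_high:g}] Hz"
            )
    in_band = agent.frequencies[
        (agent.frequencies >= plan.f_low) & (agent.frequencies <= plan.f_high)
    ]
    grid = np.unique(np.concatenate([in_band, plan.edges]))
    ref_aligned = resample_to_grid(reference, grid)

    a = slope_profile(agent, plan).local_slopes
    r = slope_profile(ref_aligned, plan).local_slopes
    d = a - r
    bits = tuple(0 if abs(x) <= tie_tolerance else (1 if x > 0 else -1) for x in d)
    return Fingerprint(
        bits=bits,
        scheme=TERNARY,
        plan=plan,
        tie_tolerance=tie_tolerance,
        reference_label=reference.label or "reference",
        label=agent.label,
    )


def alphabet_entropy(scheme: str) -> float:
    """Bits per symbol of a fingerprint alphabet under a uniform symbol model.

    ``binary`` -> 1.0; ``ternary`` -> log2(3) ~ 1.585.
    """
    if scheme == BINARY:
        return 1.0
    if scheme == TERNARY:
        return math.log2(3)
    raise ValidationError(f"unknown scheme {scheme!r}; expected 'binary' or 'ternary'")


def entropy_increase() -> float:
    """Percent entropy gain of a ternary symbol over a binary one.

    ``100 * (log2 3 - 1) ~ 58.5`` — a ternary bit carries ``ln 3 / ln 2``
    times the information of a binary bit.
    """
    return 100.0 * (math.log2(3) - 1.0)
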