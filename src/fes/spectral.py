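"""Power density spectrum estimation and conditioning.

This module is the "spectrum analyzer" stage of a fluctuation-enhanced
sensing chain: it turns a sensor-noise voltage trace into a smoothed,
band-limited one-sided power density spectrum (PSD) suitable for log-log
slope analysis.

The estimator is Welch's averaged periodogram (:func:`scipy.signal.welch`)
with per-segment mean removal. The DC bin is always dropped — the log-log
slope analysis downstream is undefined at ``f = 0``.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .errors import BandError, ExtrapolationError, SizingError, ValidationError
from .types import PowerSpectrum, TimeSeriesRecord

__all__ = [
    "estimate_psd",
    "log_bin_spectrum",
    "select_band",
    "resample_to_grid",
    "default_band",
    "DEFAULT_SEGMENT_LENGTH",
    "DEFAULT_OVERLAP",
    "DEFAULT_WINDOW",
    "DEFAULT_BINS_PER_DECADE",
]

DEFAULT_SEGMENT_LENGTH = 4096
DEFAULT_OVERLAP = 0.5
DEFAULT_WINDOW = "hann"
DEFAULT_BINS_PER_DECADE = 12


def estimate_psd(
    ts: TimeSeriesRecord,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP,
    window_name: str = DEFAULT_WINDOW,
) -> PowerSpectrum:
    """Estimate the one-sided PSD of a noise record by Welch averaging.

    Parameters
    ----------
    ts : TimeSeriesRecord
        The sensor-noise voltage trace.
    segment_length : int
        Samples per Welch segment (>= 16 and <= len(ts)). The record must be
        at least two segments long so that averaging is possible.
    overlap_fraction : float
        Fractional overlap between consecutive segments, in ``[0, 1)``.
    window_name : str
        Any window name accepted by :func:`scipy.signal.get_window`.

    Returns
    -------
    PowerSpectrum
        Averaged one-sided density in power/Hz with the DC bin removed and
        the number of averaged segments recorded in ``n_averages``.
    """
    segment_length = int(segment_length)
    if segment_length < 16:
        raise ValidationError("segment_length must be >= 16")
    if not 0 <= overlap_fraction < 1:
        raise ValidationError("overlap_fraction must be in [0, 1)")
    n = len(ts)
    if n < 2 * segment_length:
        raise SizingError(
            f"series of {n} samples is shorter than two segments of "
            f"{segment_length}; PSD averaging impossible"
        )
    noverlap = int(round(overlap_fraction * segment_length))
    if noverlap >= segment_length:  # guard round-up at overlap ~ 1
        noverlap = segment_length - 1
    freqs, psd = signal.welch(
        ts.samples,
        fs=ts.sampling_rate,
        window=window_name,
        nperseg=segment_length,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    n_averages = 1 + (n - segment_length) // (segment_length - noverlap)
    # drop DC; Welch output is otherwise strictly positive for noise input
    return PowerSpectrum(
        frequencies=freqs[1:],
        density=psd[1:],
        n_averages=n_averages,
        label=ts.label,
    )


def log_bin_spectrum(
    ps: PowerSpectrum, bins_per_decade: int = DEFAULT_BINS_PER_DECADE
) -> PowerSpectrum:
    """Smooth a spectrum onto a logarithmic frequency grid.

    Points are grouped into bins of equal width in ``log10(f)``; each
    non-empty bin is reduced to its geometric-mean frequency and
    arithmetic-mean density. Smoothing keeps local chord slopes from being
    dominated by single-bin estimator scatter; a pure power law passes
    through unchanged in slope.
    """
    bins_per_decade = int(bins_per_decade)
    if bins_per_decade < 1:
        raise ValidationError("bins_per_decade must be >= 1")
    logf = np.log10(ps.frequencies)
    width = 1.0 / bins_per_decade
    # bin indices relative to the lowest frequency; final bin right-closed so
    # the top endpoint never sits alone in an extra bin
    idx = np.floor((logf - logf[0]) / width).astype(int)
    span = logf[-1] - logf[0]
    n_bins = max(1, int(np.ceil(span / width - 1e-12)))
    idx = np.minimum(idx, n_bins - 1)
    out_f, out_s = [], []
    for k in np.unique(idx):
        m = idx == k
        out_f.append(10.0 ** np.mean(logf[m]))
        out_s.append(float(np.mean(ps.density[m])))
    if len(out_f) < 2:
        raise BandError(
            f"log binning at {bins_per_decade} bins/decade leaves "
            f"{len(out_f)} point(s); need >= 2"
        )
    return PowerSpectrum(
        frequencies=np.asarray(out_f),
        density=np.asarray(out_s),
        n_averages=ps.n_averages,
        label=ps.label,
    )


def select_band(ps: PowerSpectrum, f_low: float, f_high: float) -> PowerSpectrum:
    """Restrict a spectrum to the closed band ``[f_low, f_high]``."""
    if not (0 < f_low < f_high):
        raise BandError(f"need 0 < f_low < f_high, got [{f_low}, {f_high}]")
    mask = (ps.frequencies >= f_low) & (ps.frequencies <= f_high)
    if int(mask.sum()) < 2:
        raise BandError(
            f"band [{f_low:g}, {f_high:g}] Hz keeps {int(mask.sum())} point(s) of a "
            f"spectrum supported on [{ps.f_min:g}, {ps.f_max:g}] Hz; need >= 2"
        )
    return PowerSpectrum(
        frequencies=ps.frequencies[mask],
        density=ps.density[mask],
        n_averages=ps.n_averages,
        label=ps.label,
    )


def resample_to_grid(
    ps: PowerSpectrum, target_frequencies: Sequence[float]
) -> PowerSpectrum:
    """Resample a spectrum onto new frequencies by log-log interpolation.

    Interpolation is linear in ``log10(density)`` versus ``log10(frequency)``,
    so pure power laws are reproduced exactly at any interior target. No
    extrapolation: every target must lie within the source support.
    """
    targets = np.atleast_1d(np.asarray(target_frequencies, dtype=float))
    if targets.size < 2:
        raise ValidationError("need at least 2 target frequencies")
    if not np.all(np.diff(targets) > 0) or targets[0] <= 0:
        raise ValidationError("target frequencies must be positive and strictly ascending")
    # tiny relative slack so a target equal to an endpoint survives float noise
    rtol = 1e-12
    if targets[0] < ps.f_min * (1 - rtol) or targets[-1] > ps.f_max * (1 + rtol):
        raise ExtrapolationError(
            f"targets [{targets[0]:g}, {targets[-1]:g}] Hz exceed the source "
            f"support [{ps.f_min:g}, {ps.f_max:g}] Hz; extrapolation refused"
        )
    targets = np.clip(targets, ps.f_min, ps.f_max)
    log_s = np.interp(
        np.log10(targets), np.log10(ps.frequencies), np.log10(ps.density)
    )
    return PowerSpectrum(
        frequencies=targets,
        density=10.0 ** log_s,
        n_averages=ps.n_averages,
        label=ps.label,
    )


def default_band(ps: PowerSpectrum, nyquist: Optional[float] = None) -> Tuple[float, float]:
    """The default "meaningful" analysis band for a spectrum.

    ``[2 x lowest retained frequency, 0.8 x Nyquist]`` — the noisiest lowest
    bin and the anti-aliasing roll-off are discarded. If the Nyquist
    frequency is unknown the spectrum's top frequency stands in for it.
    Always overridable: the meaningful band is an operator choice.
    """
    top = 0.8 * (nyquist if nyquist is not None else ps.f_max)
    lo = 2.0 * ps.f_min
    if lo >= top:
        raise BandError(
            f"default band [{lo:g}, {top:g}] Hz is empty; pass an explicit band"
        )
    return lo, top
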