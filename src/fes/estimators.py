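"""scikit-learn-compatible estimators for batched fingerprinting.

The library's core operations work on single domain objects (one record, one
spectrum). When many records of equal length and sampling rate are analysed
at once — the usual shape of a sensor-array screening experiment — the chain
is transform/predict shaped and composes naturally with scikit-learn:

    Pipeline([
        ("psd", WelchSpectrumTransformer(sampling_rate=1000.0)),
        ("fp",  SlopeFingerprintTransformer(reference=ref_spectrum)),
        ("id",  NearestFingerprintClassifier()),
    ])

``WelchSpectrumTransformer`` maps an ``(n_records, n_samples)`` matrix of
noise traces to an ``(n_records, n_frequencies)`` matrix of band-limited
log-binned PSDs; ``SlopeFingerprintTransformer`` maps PSD rows to fingerprint
symbol rows in ``{-1, 0, +1}``; ``NearestFingerprintClassifier`` is a
Hamming-distance nearest-neighbour labeller that refuses silent tie-breaks.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import fingerprint as fp
from . import spectral
from .errors import ValidationError
from .types import BandPlan, PowerSpectrum, TimeSeriesRecord

__all__ = [
    "WelchSpectrumTransformer",
    "SlopeFingerprintTransformer",
    "NearestFingerprintClassifier",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D (n_records, n_samples) array")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    return X


class WelchSpectrumTransformer(TransformerMixin, BaseEstimator):
    """Rows of noise samples -> rows of band-limited, log-binned PSD values.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate of every row, in Hz.
    segment_length, overlap_fraction, window_name :
        Welch settings (see :func:`fes.spectral.estimate_psd`).
    log_bins_per_decade : int or None
        Log-grid smoothing; ``None`` keeps the raw Welch grid.
    band : (f_low, f_high) or None
        Analysis band; ``None`` selects the default meaningful band
        (2 x lowest bin to 0.8 x Nyquist).

    Attributes
    ----------
    frequencies_ : ndarray
        The common output frequency grid (fixed by the settings, Hz).
    band_ : tuple of float
        The resolved analysis band (Hz).
    """

    def __init__(
        self,
        sampling_rate: float = 1000.0,
        segment_length: int = spectral.DEFAULT_SEGMENT_LENGTH,
        overlap_fraction: float = spectral.DEFAULT_OVERLAP,
        window_name: str = spectral.DEFAULT_WINDOW,
        log_bins_per_decade: Optional[int] = spectral.DEFAULT_BINS_PER_DECADE,
        band: Optional[Tuple[float, float]] = None,
    ):
        self.sampling_rate = sampling_rate
        self.segment_length = segment_length
        self.overlap_fraction = overlap_fraction
        self.window_name = window_name
        self.log_bins_per_decade = log_bins_per_decade
        self.band = band

    def _one(self, row: np.ndarray) -> PowerSpectrum:
        ts = TimeSeriesRecord(samples=row, sampling_rate=self.sampling_rate)
        ps = spectral.estimate_psd(
            ts, self.segment_length, self.overlap_fraction, self.window_name
        )
        if self.log_bins_per_decade is not None:
            ps = spectral.log_bin_spectrum(ps, self.log_bins_per_decade)
        band = self.band or spectral.default_band(ps, nyquist=ts.nyquist)
        return spectral.select_band(ps, *band)

    def fit(self, X, y=None):
        X = _as_matrix(X)
        first = self._one(X[0])
        self.frequencies_ = first.frequencies.copy()
        self.band_ = (first.f_min, first.f_max)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "frequencies_")
        X = _as_matrix(X)
        out = np.empty((X.shape[0], self.frequencies_.size))
        for i, row in enumerate(X):
            ps = self._one(row)
            if ps.frequencies.size != self.frequencies_.size or not np.allclose(
                ps.frequencies, self.frequencies_
            ):
                raise ValidationError(
                    "record produces a different frequency grid than the fitted one "
                    "(unequal length or sampling rate?)"
                )
            out[i] = ps.density
        return out

    def spectra(self, X) -> list:
        """Transform to a list of :class:`PowerSpectrum` objects (with grid)."""
        check_is_fitted(self, "frequencies_")
        return [self._one(row) for row in _as_matrix(X)]


class SlopeFingerprintTransformer(TransformerMixin, BaseEstimator):
    """Rows of PSD values -> rows of fingerprint symbols in {-1, 0, +1}.

    Needs the frequency grid of the PSD rows: either pass ``frequencies`` at
    construction or fit after a :class:`WelchSpectrumTransformer` inside a
    ``Pipeline`` (the grid is then taken from that step's output metadata via
    ``set_frequencies``). Binary scheme when ``reference`` is ``None``;
    ternary relative to the reference spectrum otherwise.
    """

    def __init__(
        self,
        frequencies: Optional[Sequence[float]] = None,
        n_subbands: int = fp.DEFAULT_N_SUBBANDS,
        band: Optional[Tuple[float, float]] = None,
        reference: Optional[PowerSpectrum] = None,
        tie_tolerance: float = fp.DEFAULT_TIE_TOLERANCE,
    ):
        self.frequencies = frequencies
        self.n_subbands = n_subbands
        self.band = band
        self.reference = reference
        self.tie_tolerance = tie_tolerance

    def set_frequencies(self, frequencies: Sequence[float]) -> "SlopeFingerprintTransformer":
        """Set the PSD grid after construction (e.g. from an upstream step)."""
        self.frequencies = np.asarray(frequencies, dtype=float)
        return self

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.frequencies is None:
            raise ValidationError(
                "frequencies must be set (constructor or set_frequencies) "
                "before fitting"
            )
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.size != X.shape[1]:
            raise ValidationError(
                f"X has {X.shape[1]} columns but {freqs.size} frequencies given"
            )
        # requested band intersected with the grid support: a log-binned grid
        # cannot carry points exactly at the requested edges
        lo, hi = self.band or (float(freqs[0]), float(freqs[-1]))
        lo, hi = max(lo, float(freqs[0])), min(hi, float(freqs[-1]))
        if not lo < hi:
            raise ValidationError(
                f"band [{lo:g}, {hi:g}] Hz does not overlap the grid support"
            )
        self.plan_: BandPlan = fp.make_band_plan(lo, hi, self.n_subbands)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "plan_")
        X = _as_matrix(X)
        freqs = np.asarray(self.frequencies, dtype=float)
        out = np.empty((X.shape[0], self.plan_.n_subbands), dtype=int)
        for i, row in enumerate(X):
            ps = PowerSpectrum(frequencies=freqs, density=row)
            if self.reference is None:
                f = fp.binary_fingerprint(ps, self.plan_)
            else:
                f = fp.ternary_fingerprint(
                    ps, self.reference, self.plan_, self.tie_tolerance
                )
            out[i] = f.bits
        return out


class NearestFingerprintClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-neighbour labeller over fingerprint symbol rows.

    ``fit`` stores the labelled fingerprints; ``predict`` returns, per query
    row, the label whose stored fingerprint has the smallest Hamming count.
    Ties are never broken silently: ``predict`` raises unless
    ``on_tie='first'`` (lexicographically smallest label) is requested
    explicitly; ``candidates`` always exposes the full tie set.
    """

    def __init__(self, on_tie: str = "raise"):
        self.on_tie = on_tie

    def fit(self, X, y):
        X = np.asarray(X, dtype=int)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be (n_entries, n_bits) matching y")
        if not set(np.unique(X)) <= {-1, 0, 1}:
            raise ValidationError("fingerprint symbols must be in {-1, 0, +1}")
        if len(set(y.tolist())) != len(y):
            raise ValidationError("library labels must be unique")
        if self.on_tie not in ("raise", "first"):
            raise ValidationError("on_tie must be 'raise' or 'first'")
        self.X_ = X
        self.classes_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=int)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.X_.shape[1]:
            raise ValidationError(
                f"query has {X.shape[1]} bits, library has {self.X_.shape[1]}"
            )
        return (X[:, None, :] != self.X_[None, :, :]).sum(axis=2)

    def candidates(self, X) -> list:
        """Per query row: (tuple of tied nearest labels, distance)."""
        d = self._distances(X)
        out = []
        for row in d:
            best = int(row.min())
            labels = tuple(sorted(self.classes_[row == best].tolist()))
            out.append((labels, best))
        return out

    def predict(self, X) -> np.ndarray:
        results = self.candidates(X)
        labels = []
        for tied, dist in results:
            if len(tied) > 1 and self.on_tie == "raise":
                raise ValidationError(
                    f"ambiguous match at distance {dist}: {list(tied)} "
                    f"(use on_tie='first' to accept the lexicographic winner)"
                )
            labels.append(tied[0])
        return np.asarray(labels)
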