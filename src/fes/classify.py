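"""Fingerprint comparison and nearest-fingerprint identification.

A fingerprint acts as an address for the name of a chemical environment: an
exact lookup in a labelled library identifies the odor.  Real repeated
measurements rarely reproduce every bit, so the library lookup here is a
nearest-neighbour match under the Hamming count, with ties *surfaced*, never
broken silently — ambiguity is part of the answer.

``bit_agreement`` (fraction of identical positions between two fingerprints
of the same sample) is the reproducibility statistic used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import CompatibilityError, ValidationError
from .types import BandPlan, Fingerprint

__all__ = [
    "fingerprint_distance",
    "weighted_fingerprint_distance",
    "bit_agreement",
    "classify",
    "ClassificationResult",
    "FingerprintLibrary",
]


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if a.scheme != b.scheme:
        raise CompatibilityError(
            f"scheme mismatch: {a.scheme!r} vs {b.scheme!r}"
        )
    if len(a) != len(b):
        raise CompatibilityError(f"length mismatch: {len(a)} vs {len(b)}")
    if a.plan != b.plan:
        raise CompatibilityError(
            f"band plan mismatch: edges {np.round(a.plan.edges, 6).tolist()} "
            f"vs {np.round(b.plan.edges, 6).tolist()}"
        )


def fingerprint_distance(a: Fingerprint, b: Fingerprint) -> int:
    """Number of positions where two compatible fingerprints differ.

    The plain Hamming count over the symbol alphabet: a 0 vs ±1 mismatch
    counts the same as a +1 vs −1 sign flip (the minimal assumption; see
    :func:`weighted_fingerprint_distance` for the graded variant).
    """
    _check_compatible(a, b)
    return int(sum(x != y for x, y in zip(a.bits, b.bits)))


def weighted_fingerprint_distance(a: Fingerprint, b: Fingerprint) -> int:
    """Graded distance: a +1 vs −1 sign flip costs 2, a 0 vs ±1 step costs 1.

    Non-default alternative to :func:`fingerprint_distance`; equals it on
    binary fingerprints scaled by 2.
    """
    _check_compatible(a, b)
    return int(sum(abs(x - y) for x, y in zip(a.bits, b.bits)))


def bit_agreement(a: Fingerprint, b: Fingerprint) -> float:
    """Fraction of identical positions, ``1 - distance/length``, in [0, 1]."""
    return 1.0 - fingerprint_distance(a, b) / len(a)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of a nearest-fingerprint lookup.

    ``labels`` holds every library label at the minimum distance; a unique
    match gives one label and ``ambiguous=False``.
    """

    labels: Tuple[str, ...]
    distance: int
    ambiguous: bool

    @property
    def label(self) -> str:
        """The matched label; raises if the match is ambiguous."""
        if self.ambiguous:
            raise ValidationError(
                f"ambiguous match at distance {self.distance}: {list(self.labels)}"
            )
        return self.labels[0]


class FingerprintLibrary:
    """A labelled collection of mutually compatible fingerprints.

    All entries must share scheme, bit length, band edges and — for ternary
    fingerprints — the reference identity; labels are unique.
    """

    def __init__(self, entries: Dict[str, Fingerprint]):
        if not entries:
            raise ValidationError("library must contain at least one fingerprint")
        items = list(entries.items())
        first = items[0][1]
        for label, fp in items[1:]:
            try:
                _check_compatible(first, fp)
            except CompatibilityError as e:
                raise CompatibilityError(f"library entry {label!r}: {e}") from e
            if (
                fp.scheme == "ternary"
                and fp.reference_label != first.reference_label
            ):
                raise CompatibilityError(
                    f"library entry {label!r}: reference {fp.reference_label!r} "
                    f"differs from {first.reference_label!r}"
                )
        self._entries: Dict[str, Fingerprint] = dict(items)

    @property
    def entries(self) -> Dict[str, Fingerprint]:
        return dict(self._entries)

    @property
    def scheme(self) -> str:
        return next(iter(self._entries.values())).scheme

    @property
    def plan(self) -> BandPlan:
        return next(iter(self._entries.values())).plan

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __getitem__(self, label: str) -> Fingerprint:
        return self._entries[label]


def classify(query: Fingerprint, library: FingerprintLibrary) -> ClassificationResult:
    """Identify a query fingerprint by nearest library entry.

    Returns the label(s) minimising :func:`fingerprint_distance`. Sorting of
    tied labels is lexicographic purely for presentation; the result is
    invariant to the library's insertion order.
    """
    distances = {
        label: fingerprint_distance(query, fp)
        for label, fp in library.entries.items()
    }
    best = min(distances.values())
    winners = tuple(sorted(l for l, d in distances.items() if d == best))
    return ClassificationResult(
        labels=winners, distance=best, ambiguous=len(winners) > 1
    )
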