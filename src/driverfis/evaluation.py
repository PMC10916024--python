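"""Benchmark metrics for called driver-gene sets.

Overlap fraction against curated panels (CGC-style lists), consensus with
other methods' predictions, dispersion of per-cohort driver counts, and
Jaccard stability under subsampling. Symbols are matched exactly after
uppercasing and whitespace stripping; metrics that are undefined on empty
input return ``None`` rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GenePanel",
    "read_panel",
    "overlap_fraction",
    "method_consensus",
    "count_dispersion",
    "jaccard_stability",
]


def _normalize(symbols: Iterable[str]) -> frozenset[str]:
    return frozenset(s.strip().upper() for s in symbols if str(s).strip())


@dataclass(frozen=True)
class GenePanel:
    """A named reference gene panel (e.g. CGC, Mut-driver, HiConf)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", _normalize(self.members))
        if not self.members:
            raise ValueError(f"panel {self.name!r} is empty")


def read_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Read a one-symbol-per-line panel file."""
    path = Path(path)
    return GenePanel(name or path.stem, frozenset(path.read_text().split()))


def overlap_fraction(
    identified: Iterable[str], panel: GenePanel, min_genes: int = 0
) -> Optional[float]:
    """Fraction of identified genes present in the panel.

    Returns ``None`` for an empty identified set. ``min_genes`` reproduces
    the comparison protocol that scores a method 0 when it predicts fewer
    than that many genes.
    """
    ident = _normalize(identified)
    if not ident:
        return None
    if min_genes and len(ident) < min_genes:
        return 0.0
    return len(ident & panel.members) / len(ident)


def method_consensus(
    identified: Iterable[str],
    other_methods: Sequence[Iterable[str]],
    t: int = 1,
) -> Optional[float]:
    """Fraction of identified genes predicted by at least ``t`` other methods."""
    if t < 1:
        raise ValueError("t must be >= 1")
    ident = _normalize(identified)
    if not ident:
        return None
    others = [_normalize(m) for m in other_methods]
    hits = sum(1 for g in ident if sum(g in m for m in others) >= t)
    return hits / len(ident)


def count_dispersion(driver_counts: Sequence[float]) -> float:
    """Sample standard deviation (n-1) of per-cohort driver counts."""
    counts = np.asarray(driver_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need counts from at least two cohorts")
    return float(np.std(counts, ddof=1))


def jaccard_stability(
    original: Iterable[str], resampled: Iterable[str]
) -> Optional[float]:
    """Jaccard similarity |A ∩ B| / |A ∪ B| of two driver sets.

    ``None`` when both sets are empty (undefined ratio).
    """
    a, b = _normalize(original), _normalize(resampled)
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)
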