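"""Observed per-gene functional-impact scores.

Mutations whose FIS could not be looked up are filled from the cohort mean
of observed scores in the same effect class; effect classes with no observed
score at all fall back to fixed constants reflecting the typical severity
ordering (silent 0 < noncoding 1 < nonsilent 2 < null 3). Each gene's
observed score y_g is then the sum of its mutations' filled scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .maf_io import Effect, MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FALLBACK_FIS",
    "GeneFISSummary",
    "fill_missing_fis",
    "summarize_gene",
    "summarize_cohort",
    "cohort_sample_count",
]

#: per-effect constants used when an effect class has no observed score
FALLBACK_FIS = {
    Effect.SILENT: 0.0,
    Effect.NONCODING: 1.0,
    Effect.NONSILENT: 2.0,
    Effect.NULL: 3.0,
}


@dataclass(frozen=True, slots=True)
class GeneFISSummary:
    """Per-gene observed FIS total and mutation/sample counts.

    ``m_harm_mut`` counts harmful (nonsilent/null) mutations;
    ``m_harm_samples`` counts distinct samples carrying at least one harmful
    mutation in the gene; ``M`` is the cohort sample count.
    """

    gene: str
    y_obs: float
    m_total: int
    m_harm_mut: int
    m_harm_samples: int
    M: int

    def __post_init__(self) -> None:
        if not (0 <= self.m_harm_mut <= self.m_total):
            raise ValueError(f"{self.gene}: m_harm_mut outside [0, m_total]")
        if not (0 <= self.m_harm_samples <= min(self.m_harm_mut, self.M)):
            raise ValueError(f"{self.gene}: m_harm_samples inconsistent")


def fill_missing_fis(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Fill missing FIS values from cohort effect-class means.

    The class means are computed once, from pre-fill observed scores only,
    so filling is idempotent and order-independent. Classes with zero
    observed scores use :data:`FALLBACK_FIS`. Records with effect ``ignore``
    are passed through untouched (they are excluded downstream).
    """
    records = list(records)
    observed: dict[Effect, list[float]] = {e: [] for e in FALLBACK_FIS}
    for r in records:
        if r.effect in FALLBACK_FIS and r.fis is not None:
            observed[r.effect].append(r.fis)
    class_fill = {
        e: (sum(v) / len(v) if v else FALLBACK_FIS[e]) for e, v in observed.items()
    }
    filled = 0
    out: list[MutationRecord] = []
    for r in records:
        if r.fis is None and r.effect in class_fill:
            out.append(replace(r, fis=class_fill[r.effect]))
            filled += 1
        else:
            out.append(r)
    if filled:
        logger.info("fill_missing_fis: filled %d/%d records", filled, len(records))
    return out


def cohort_sample_count(records: Iterable[MutationRecord]) -> int:
    """M = number of distinct sample identifiers in the mutation table."""
    return len({r.sample_id for r in records})


def summarize_gene(
    records: Sequence[MutationRecord], M: int, gene: Optional[str] = None
) -> GeneFISSummary:
    """Summarize one gene's mutations into a :class:`GeneFISSummary`.

    All records must belong to one gene, carry a filled FIS and a concrete
    effect class (``ignore`` records must be filtered before calling).
    """
    if M <= 0:
        raise ValueError("cohort sample count M must be positive")
    recs = [r for r in records if r.effect is not Effect.IGNORE]
    if not recs:
        raise ValueError("no records to summarize")
    symbols = {r.gene for r in recs}
    if gene is None:
        if len(symbols) != 1:
            raise ValueError(f"records span multiple genes: {sorted(symbols)}")
        gene = next(iter(symbols))
    if any(r.fis is None for r in recs):
        raise ValueError(f"{gene}: unfilled FIS; run fill_missing_fis first")
    harmful = [r for r in recs if r.effect.is_harmful]
    return GeneFISSummary(
        gene=gene,
        y_obs=float(sum(r.fis for r in recs)),
        m_total=len(recs),
        m_harm_mut=len(harmful),
        m_harm_samples=len({r.sample_id for r in harmful}),
        M=M,
    )


def summarize_cohort(
    records: Iterable[MutationRecord], M: Optional[int] = None
) -> pd.DataFrame:
    """Per-gene summary table (gene-sorted) for the whole cohort.

    Genes under study are exactly the genes with at least one non-ignored
    mutation. Returns columns y_obs, m_total, m_harm_mut, m_harm_samples, M.
    """
    records = list(records)
    if M is None:
        M = cohort_sample_count(records)
    by_gene: dict[str, list[MutationRecord]] = {}
    for r in records:
        if r.effect is Effect.IGNORE:
            continue
        by_gene.setdefault(r.gene, []).append(r)
    if not by_gene:
        raise ValueError("no genes under study (empty or all-ignored cohort)")
    rows = [summarize_gene(v, M, gene=g) for g, v in sorted(by_gene.items())]
    df = pd.DataFrame(
        [
            (s.gene, s.y_obs, s.m_total, s.m_harm_mut, s.m_harm_samples, s.M)
            for s in rows
        ],
        columns=["gene", "y_obs", "m_total", "m_harm_mut", "m_harm_samples", "M"],
    ).set_index("gene")
    return df
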