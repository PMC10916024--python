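"""Reading MAF mutation tables and annotating functional-impact scores.

Somatic mutation calls arrive as MAF (Mutation Annotation Format) tables:
tab-separated, one row per mutation, 1-based inclusive coordinates. Each
variant classification (``Missense_Mutation``, ``Silent``, ...) is collapsed
to one of four mutation-effect classes — silent, nonsilent, noncoding, null —
via an editable dictionary file, and single-nucleotide substitutions are
matched against a per-substitution functional-impact score (FIS) lookup
table in the MutationAssessor export style (chrom, position, ref, alt,
score).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "MutationRecord",
    "EffectDictionary",
    "FisTable",
    "read_maf",
    "write_maf",
    "map_effect",
    "apply_effects",
    "annotate_fis",
    "load_effect_dictionary",
    "load_fis_table",
]


class Effect(enum.Enum):
    """Mutation-effect classes; ``harmful`` = nonsilent or null."""

    SILENT = "silent"
    NONSILENT = "nonsilent"
    NONCODING = "noncoding"
    NULL = "null"
    IGNORE = "ignore"

    @property
    def is_harmful(self) -> bool:
        return self in (Effect.NONSILENT, Effect.NULL)


#: canonical MAF column -> accepted header aliases (first match wins)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "sample_id": ("Tumor_Sample_Barcode", "sample", "Sample_ID"),
    "gene": ("Hugo_Symbol", "gene", "Gene"),
    "chrom": ("Chromosome", "chrom", "chr"),
    "start_pos": ("Start_position", "Start_Position", "start"),
    "end_pos": ("End_position", "End_Position", "end"),
    "ref_allele": ("Reference_Allele", "ref"),
    "alt_allele": ("Tumor_Seq_Allele2", "Tumor_Seq_Allele1", "alt"),
    "variant_classification": ("Variant_Classification",),
}

#: columns that must resolve to some alias in the header
REQUIRED = (
    "sample_id",
    "gene",
    "chrom",
    "start_pos",
    "ref_allele",
    "alt_allele",
    "variant_classification",
)

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One annotated somatic mutation.

    Coordinates are 1-based inclusive; ``chrom`` is normalized (no ``chr``
    prefix, ``MT`` -> ``M``). ``fis`` is ``None`` until annotated/filled.
    """

    sample_id: str
    gene: str
    chrom: str
    start_pos: int
    end_pos: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    effect: Optional[Effect] = None
    fis: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError(
                f"start_pos {self.start_pos} > end_pos {self.end_pos} "
                f"for {self.gene} ({self.chrom})"
            )

    @property
    def is_snv(self) -> bool:
        """True for single-nucleotide substitutions (the only FIS-lookup keys)."""
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _NUCLEOTIDES
            and self.alt_allele in _NUCLEOTIDES
        )


def normalize_chrom(label: str, numeric_xy: bool = False) -> str:
    """Normalize a chromosome label: strip ``chr``, ``MT``->``M``.

    With ``numeric_xy``, ``23``/``24`` map to ``X``/``Y`` (some pipelines
    emit numeric sex chromosomes).
    """
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() == "MT":
        c = "M"
    if numeric_xy:
        c = {"23": "X", "24": "Y"}.get(c, c)
    return c.upper() if c.upper() in ("X", "Y", "M") else c


def _resolve_columns(
    header: Sequence[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    for canonical, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[canonical] = lower[name.lower()]
                break
    return resolved


def read_maf(
    path: str | Path,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
    numeric_xy: bool = False,
    dedup: bool = False,
) -> list[MutationRecord]:
    """Parse a MAF file into :class:`MutationRecord` objects.

    Raises ``ValueError`` naming the first required column whose aliases are
    all absent. Rows with unparseable coordinates are skipped with a logged
    warning. ``effect`` and ``fis`` are left unset. With ``dedup``, rows
    identical in (sample, site, alleles) are collapsed to one.
    """
    aliases = dict(DEFAULT_ALIASES, **(aliases or {}))
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, aliases)
    absent = [aliases[c][0] for c in REQUIRED if c not in cols]
    if absent:
        raise ValueError(f"MAF file {path} lacks required column(s): {absent}")

    records: list[MutationRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda canon: r[cols[canon]]
        try:
            start = int(float(get("start_pos")))
            end = int(float(get("end_pos"))) if "end_pos" in cols else start
        except (ValueError, TypeError):
            skipped += 1
            continue
        records.append(
            MutationRecord(
                sample_id=str(get("sample_id")).strip(),
                gene=str(get("gene")).strip(),
                chrom=normalize_chrom(get("chrom"), numeric_xy=numeric_xy),
                start_pos=start,
                end_pos=end,
                ref_allele=str(get("ref_allele")).strip().upper(),
                alt_allele=str(get("alt_allele")).strip().upper(),
                variant_classification=str(get("variant_classification")).strip(),
            )
        )
    if skipped:
        logger.warning("read_maf: skipped %d rows with unparseable coordinates", skipped)
    if dedup:
        seen: set[tuple] = set()
        unique = []
        for rec in records:
            key = (rec.sample_id, rec.chrom, rec.start_pos, rec.end_pos,
                   rec.ref_allele, rec.alt_allele)
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        records = unique
    logger.info("read_maf: %d records from %s", len(records), path)
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records back to a MAF file (canonical column names; round-trips
    with :func:`read_maf`)."""
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Tumor_Sample_Barcode": r.sample_id,
            "Chromosome": r.chrom,
            "Start_position": r.start_pos,
            "End_position": r.end_pos,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Classification": r.variant_classification,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class EffectDictionary:
    """Case-insensitive mapping from MAF variant classifications to effects.

    Unmapped classifications fall back to a configurable effect (default
    ``ignore``, logged once per unseen classification).
    """

    def __init__(
        self,
        entries: Mapping[str, Effect],
        fallback: Effect = Effect.IGNORE,
    ) -> None:
        self.entries = {k.strip().lower(): v for k, v in entries.items()}
        self.fallback = fallback
        self._warned: set[str] = set()

    def lookup(self, variant_classification: str) -> Effect:
        key = variant_classification.strip().lower()
        if key in self.entries:
            return self.entries[key]
        if key not in self._warned:
            logger.warning(
                "unmapped variant classification %r -> %s",
                variant_classification, self.fallback.value,
            )
            self._warned.add(key)
        return self.fallback


def load_effect_dictionary(
    path: str | Path | None = None, fallback: Effect = Effect.IGNORE
) -> EffectDictionary:
    """Load a two-column TSV (classification, effect); default is the shipped
    dictionary patterned on the MutSigCV mutation-type dictionary."""
    if path is None:
        source = resources.files("driverfis.data") / "effect_dictionary.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    entries: dict[str, Effect] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        classification, effect = line.split("\t")
        entries[classification] = Effect(effect.strip().lower())
    return EffectDictionary(entries, fallback=fallback)


def map_effect(variant_classification: str, dictionary: EffectDictionary) -> Effect:
    """Map one classification string to its effect class (total via fallback)."""
    return dictionary.lookup(variant_classification)


def apply_effects(
    records: Iterable[MutationRecord], dictionary: EffectDictionary
) -> list[MutationRecord]:
    """Return records with ``effect`` set from the dictionary."""
    return [replace(r, effect=map_effect(r.variant_classification, dictionary))
            for r in records]


class FisTable:
    """Substitution-level FIS lookup keyed by (chrom, pos, ref, alt)."""

    def __init__(self, scores: Mapping[tuple[str, int, str, str], float]):
        self.scores = dict(scores)

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> Optional[float]:
        return self.scores.get((chrom, pos, ref, alt))


def load_fis_table(path: str | Path) -> FisTable:
    """Load a MutationAssessor-style export (chrom, pos, ref, alt, score);
    tab- or comma-separated, sniffed from the header line. Duplicate keys
    keep the last value (logged)."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    chrom_c, pos_c, ref_c, alt_c, score_c = df.columns[:5]
    scores: dict[tuple[str, int, str, str], float] = {}
    dups = 0
    for chrom, pos, ref, alt, score in zip(
        df[chrom_c], df[pos_c], df[ref_c], df[alt_c], df[score_c]
    ):
        key = (normalize_chrom(chrom), int(pos), str(ref).upper(), str(alt).upper())
        if key in scores:
            dups += 1
        scores[key] = float(score)
    if dups:
        logger.warning("load_fis_table: %d duplicate keys (last value kept)", dups)
    return FisTable(scores)


def annotate_fis(
    records: Iterable[MutationRecord], table: FisTable
) -> list[MutationRecord]:
    """Set ``fis`` from the lookup table for SNVs; non-SNVs and misses keep
    ``None`` (filled downstream from effect-class means). Only ``fis`` is
    touched; the match rate is logged."""
    out: list[MutationRecord] = []
    hits = 0
    for r in records:
        score = None
        if r.is_snv:
            score = table.get(r.chrom, r.start_pos, r.ref_allele, r.alt_allele)
        if score is not None:
            hits += 1
        out.append(replace(r, fis=score))
    n = len(out)
    logger.info("annotate_fis: matched %d/%d records (%.1f%%)",
                hits, n, 100.0 * hits / n if n else 0.0)
    return out
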