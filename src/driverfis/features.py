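"""The genes x 12 covariate matrix: assembly, KNN imputation, standardization.

Nine covariates are external annotations (expression level, replication
time, HiC compartment, coding-region length, missense constraint, expression
hubness, known-regulator status, CNV, methylation); three are computed from
the mutation table itself (total mutation count, harmful mutation count, and
the standard deviation of per-patient FIS totals). Missing external values
are imputed from the K nearest genes in feature space, then every column is
z-scored across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .maf_io import Effect, MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EXTERNAL_FEATURES",
    "MAF_FEATURES",
    "GeneFeatureMatrix",
    "read_feature_table",
    "compute_maf_features",
    "assemble_features",
    "euclidean_distance",
    "impute_missing",
    "standardize",
]

EXTERNAL_FEATURES = (
    "expression_level",
    "replication_time",
    "hic_metric",
    "region_length",
    "constraint_score",
    "expression_hub",
    "known_regulator",
    "cnv",
    "methylation",
)
MAF_FEATURES = ("total_mutations", "harmful_mutations", "fis_sd")


@dataclass
class GeneFeatureMatrix:
    """Ordered genes x features matrix; missing entries are NaN."""

    genes: list[str]
    feature_names: list[str]
    values: np.ndarray  # float, genes x features
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.feature_names)} features"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.feature_names)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"gene {gene!r} not in feature matrix") from None


def read_feature_table(path: str | Path) -> GeneFeatureMatrix:
    """Read the external covariate TSV: first column gene symbol, remaining
    columns the nine external covariates; empty cells are missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneFeatureMatrix(
        genes=[str(g) for g in df.index],
        feature_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def compute_maf_features(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Per-gene covariates derived from the mutation table.

    Returns a DataFrame indexed by gene with columns ``total_mutations``
    (all non-ignored mutations), ``harmful_mutations`` (nonsilent or null),
    and ``fis_sd`` — the sample standard deviation (n-1) of per-patient FIS
    totals over patients carrying at least one mutation in the gene (0 when
    a single patient carries them all). Requires effects mapped and FIS
    filled.
    """
    rows = [
        (r.gene, r.sample_id, r.effect, r.fis)
        for r in records
        if r.effect is not Effect.IGNORE
    ]
    if not rows:
        raise ValueError("no usable mutation records (empty or all ignored)")
    df = pd.DataFrame(rows, columns=["gene", "sample", "effect", "fis"])
    if df["fis"].isna().any():
        raise ValueError("records must have filled FIS before computing features")

    total = df.groupby("gene").size()
    harmful = df[df["effect"].map(lambda e: e.is_harmful)].groupby("gene").size()
    per_patient = df.groupby(["gene", "sample"])["fis"].sum()
    fis_sd = per_patient.groupby("gene").std(ddof=1).fillna(0.0)

    out = pd.DataFrame(
        {
            "total_mutations": total,
            "harmful_mutations": harmful.reindex(total.index, fill_value=0),
            "fis_sd": fis_sd.reindex(total.index, fill_value=0.0),
        }
    ).astype(float)
    out.index.name = "gene"
    return out


def assemble_features(
    maf_features: pd.DataFrame,
    external: Optional[GeneFeatureMatrix] = None,
    genes: Optional[Sequence[str]] = None,
) -> GeneFeatureMatrix:
    """Join external covariates with the MAF-derived ones into one matrix.

    ``genes`` fixes the gene universe (default: the MAF-derived index,
    sorted). Genes without an external row get NaN externals (imputed
    later); genes never mutated get zero counts.
    """
    if genes is None:
        genes = sorted(maf_features.index)
    genes = list(genes)
    names = list(external.feature_names) if external is not None else list(EXTERNAL_FEATURES)
    if external is not None:
        ext = external.to_frame().reindex(genes)
        missing_ext = int(ext.isna().all(axis=1).sum())
        if missing_ext:
            logger.info(
                "assemble_features: %d genes lack external covariates "
                "(all nine treated as missing)", missing_ext
            )
    else:
        ext = pd.DataFrame(np.nan, index=genes, columns=names)
    maf_part = maf_features.reindex(genes)
    maf_part[["total_mutations", "harmful_mutations"]] = maf_part[
        ["total_mutations", "harmful_mutations"]
    ].fillna(0.0)
    maf_part["fis_sd"] = maf_part["fis_sd"].fillna(0.0)
    values = np.hstack([ext.to_numpy(dtype=float), maf_part.to_numpy(dtype=float)])
    return GeneFeatureMatrix(
        genes=genes, feature_names=names + list(MAF_FEATURES), values=values
    )


def euclidean_distance(
    vi: np.ndarray, vj: np.ndarray, exclude: Optional[int] = None
) -> float:
    """Euclidean distance in feature space, optionally excluding one feature.

    Coordinates missing (NaN) in either vector are skipped. Raises if every
    usable coordinate pair is missing.
    """
    vi = np.asarray(vi, dtype=float)
    vj = np.asarray(vj, dtype=float)
    use = ~(np.isnan(vi) | np.isnan(vj))
    if exclude is not None:
        use[exclude] = False
    if not use.any():
        raise ValueError("no observed feature pairs in common")
    d = vi[use] - vj[use]
    return float(np.sqrt(np.sum(d * d)))


def _rescaled_for_distance(values: np.ndarray) -> np.ndarray:
    """Per-column zero-mean/unit-sd over observed entries only, so distances
    mix covariates on comparable scales; NaN preserved."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    sd = np.where((~np.isfinite(sd)) | (sd == 0), 1.0, sd)
    return (values - mean) / sd


def impute_missing(m: GeneFeatureMatrix, K: int = 100) -> GeneFeatureMatrix:
    """Fill each missing entry with the mean of its K nearest donor genes.

    For a missing entry (g, k), donors are genes with feature k observed;
    the K donors closest to g by Euclidean distance over the remaining
    features (missing-aware, computed on per-column rescaled raw values)
    supply the mean of their observed feature-k values. Ties at the K-th
    distance break lexicographically by gene symbol. Observed entries are
    never modified; imputation never chains off imputed values.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mask = m.missing_mask
    if not mask.any():
        return GeneFeatureMatrix(
            genes=list(m.genes), feature_names=list(m.feature_names),
            values=m.values.copy(), standardized=m.standardized,
        )
    fully_missing = np.nonzero(mask.all(axis=0))[0]
    if fully_missing.size:
        raise ValueError(
            f"feature {m.feature_names[fully_missing[0]]!r} is missing for every gene"
        )
    raw = m.values
    scaled = _rescaled_for_distance(raw)
    genes = np.asarray(m.genes)
    order_by_symbol = np.argsort(genes, kind="stable")

    out = raw.copy()
    for k in range(len(m.feature_names)):
        col_missing = np.nonzero(mask[:, k])[0]
        if col_missing.size == 0:
            continue
        donors = np.nonzero(~mask[:, k])[0]
        if donors.size == 0:
            raise ValueError(
                f"feature {m.feature_names[k]!r} is missing for every gene"
            )
        donor_scaled = scaled[donors]
        k_eff = min(K, donors.size)
        if k_eff < K:
            logger.warning(
                "impute_missing: only %d donors for feature %r (K lowered from %d)",
                donors.size, m.feature_names[k], K,
            )
        for g in col_missing:
            diff = donor_scaled - scaled[g]
            with np.errstate(invalid="ignore"):
                sq = diff * diff
            sq[:, k] = np.nan  # exclude the feature being imputed
            usable = (~np.isnan(sq)).sum(axis=1) > 0
            if not usable.any():
                raise ValueError(
                    f"cannot impute {m.feature_names[k]!r} for gene "
                    f"{m.genes[g]!r}: no donor shares an observed feature"
                )
            dist = np.sqrt(np.nansum(sq, axis=1))
            dist[~usable] = np.inf
            # lexsort: primary key distance, secondary gene symbol
            order = np.lexsort((genes[donors], dist))
            chosen = donors[order[: min(k_eff, int(usable.sum()))]]
            out[g, k] = raw[chosen, k].mean()
    return GeneFeatureMatrix(
        genes=list(m.genes), feature_names=list(m.feature_names), values=out
    )


def standardize(m: GeneFeatureMatrix) -> GeneFeatureMatrix:
    """Z-score each column across genes (sample sd, n-1).

    Requires a fully observed matrix; a zero-variance column is an error
    naming the feature.
    """
    if m.missing_mask.any():
        raise ValueError("standardize requires a fully observed matrix; impute first")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    degenerate = np.nonzero(sd < 1e-12)[0]
    if degenerate.size:
        names = [m.feature_names[i] for i in degenerate]
        raise ValueError(f"zero-variance feature column(s): {names}")
    return GeneFeatureMatrix(
        genes=list(m.genes),
        feature_names=list(m.feature_names),
        values=(m.values - mean) / sd,
        standardized=True,
    )
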