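"""End-to-end orchestration: MAF in, ranked driver calls out.

Stages: parse mutations -> map effects -> annotate and fill FIS ->
summarize genes -> assemble/impute/standardize covariates -> fit the
background GLM -> shrink backgrounds toward FIS-circle neighbors -> weight,
test, BH-adjust and call. A lambda sweep reuses everything up to the
(lambda-independent) circles and re-blends per lambda.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calling, observed
from .background import BackgroundModel, fit_glm, predict_bfis
from .features import (
    assemble_features,
    compute_maf_features,
    impute_missing,
    read_feature_table,
    standardize,
)
from .maf_io import (
    Effect,
    annotate_fis,
    apply_effects,
    load_effect_dictionary,
    load_fis_table,
    read_maf,
)
from .shrinkage import ShrinkageConfig, apply_shrinkage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineState", "prepare", "run_pipeline", "run_lambda_sweep"]


@dataclass
class RunConfig:
    """File paths and thresholds for one cohort run."""

    maf: str | Path
    fis_table: str | Path
    features: Optional[str | Path] = None
    effect_dictionary: Optional[str | Path] = None
    output_dir: Optional[str | Path] = None
    lambda_: float = 0.5
    K: int = 100
    n_C_max: int = 100
    q_threshold: float = 0.1
    q_cut: float = 0.05
    similarity_direction: str = "literal_le"
    skip_shrinkage: bool = False
    dedup: bool = False
    seed: int = 0

    def shrinkage_config(self, lambda_: Optional[float] = None) -> ShrinkageConfig:
        return ShrinkageConfig(
            lambda_=self.lambda_ if lambda_ is None else lambda_,
            q_threshold=self.q_threshold,
            n_C_max=self.n_C_max,
            similarity_direction=self.similarity_direction,  # type: ignore[arg-type]
        )


@dataclass
class PipelineState:
    """Everything computed before the lambda-dependent blend."""

    summaries: pd.DataFrame
    model: BackgroundModel
    y_b: pd.Series
    circles: pd.DataFrame  # circle_size, y_b, y_neighbor, y_fb at cfg.lambda_
    stage_counts: dict
    unmutated_genes: list[str]  # in the feature table but absent from the MAF


def prepare(cfg: RunConfig) -> PipelineState:
    """Run every lambda-independent stage of the pipeline."""
    records = read_maf(cfg.maf, dedup=cfg.dedup)
    M = observed.cohort_sample_count(records)
    dictionary = load_effect_dictionary(cfg.effect_dictionary)
    records = apply_effects(records, dictionary)
    records = annotate_fis(records, load_fis_table(cfg.fis_table))
    records = observed.fill_missing_fis(records)
    usable = [r for r in records if r.effect is not Effect.IGNORE]

    summaries = observed.summarize_cohort(usable, M=M)
    maf_feats = compute_maf_features(usable)
    external = read_feature_table(cfg.features) if cfg.features else None
    unmutated = (
        sorted(set(external.genes) - set(summaries.index)) if external else []
    )
    if unmutated:
        logger.info(
            "prepare: %d feature-table genes have no mutations; reported "
            "with p = 1 and flagged", len(unmutated)
        )
    feats = assemble_features(maf_feats, external, genes=list(summaries.index))
    feats = standardize(impute_missing(feats, K=cfg.K))

    y_obs = summaries["y_obs"].to_numpy()
    model = fit_glm(feats.values, y_obs, feature_names=feats.feature_names)
    y_b = pd.Series(predict_bfis(model, feats.values), index=summaries.index)

    if cfg.skip_shrinkage:
        circles = pd.DataFrame(
            {
                "circle_size": 0,
                "y_b": y_b,
                "y_neighbor": np.nan,
                "y_fb": y_b,
            },
            index=summaries.index,
        )
    else:
        circles = apply_shrinkage(feats, y_obs, y_b.to_numpy(), cfg.shrinkage_config())

    stage_counts = {
        "records_read": len(records),
        "records_usable": len(usable),
        "samples": M,
        "genes_under_study": len(summaries),
        "genes_with_circle": int((circles["circle_size"] > 0).sum()),
    }
    logger.info("prepare: %s", stage_counts)
    return PipelineState(
        summaries=summaries, model=model, y_b=y_b, circles=circles,
        stage_counts=stage_counts, unmutated_genes=unmutated,
    )


def _blend(state: PipelineState, lambda_: float) -> pd.Series:
    c = state.circles
    empty = c["circle_size"] == 0
    y_fb = lambda_ * c["y_b"] + (1.0 - lambda_) * c["y_neighbor"]
    return y_fb.where(~empty, c["y_b"])


def _results_for_lambda(
    state: PipelineState, lambda_: float, q_cut: float
) -> pd.DataFrame:
    y_fb = _blend(state, lambda_)
    results = calling.score_genes(state.summaries, y_fb, state.model.sigma0, q_cut=q_cut)
    results["y_b"] = state.y_b.reindex(results.index)
    results["y_neighbor"] = state.circles["y_neighbor"].reindex(results.index)
    results["circle_size"] = state.circles["circle_size"].reindex(results.index)
    results["in_maf"] = True
    if state.unmutated_genes:
        # feature-table genes with no mutations: flagged, p = 1, outside the
        # BH family (they are not under test and cannot become significant)
        extra = pd.DataFrame(
            {"p_value": 1.0, "q_value": 1.0, "is_driver": False,
             "in_maf": False},
            index=pd.Index(state.unmutated_genes, name="gene"),
        )
        results = pd.concat([results, extra])
    return results


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline; optionally write results plus a manifest.

    Returns the per-gene results table sorted by (q, p, gene). When
    ``cfg.output_dir`` is set, writes ``results.tsv``, ``model.json`` and a
    ``manifest.json`` recording the configuration, input checksums, stage
    counts and the fitted model, sufficient to reproduce the run.
    """
    state = prepare(cfg)
    results = _results_for_lambda(state, cfg.lambda_, cfg.q_cut)
    if cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "results.tsv", sep="\t")
        state.model.save(outdir / "model.json")
        manifest = {
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(cfg).items()
            },
            "inputs": {
                name: _sha256(p)
                for name, p in (
                    ("maf", cfg.maf),
                    ("fis_table", cfg.fis_table),
                    ("features", cfg.features),
                )
                if p is not None
            },
            "stage_counts": state.stage_counts,
            "beta": state.model.beta.tolist(),
            "sigma0": state.model.sigma0,
            "drivers_called": int(results["is_driver"].sum()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run_pipeline: %d drivers called at q <= %g",
                int(results["is_driver"].sum()), cfg.q_cut)
    return results


def run_lambda_sweep(
    cfg: RunConfig,
    lambdas: Sequence[float],
    panels: Optional[dict] = None,
) -> pd.DataFrame:
    """Re-test the cohort across shrinkage weights, reusing the fitted model.

    Circles and neighbor scores do not depend on lambda, so only the blend
    and the test are recomputed. Returns one row per lambda with the driver
    count (and overlap fractions when ``panels`` maps names to
    :class:`~driverfis.evaluation.GenePanel` objects).
    """
    if not lambdas:
        raise ValueError("at least one lambda value required")
    state = prepare(cfg)
    rows = []
    for lam in lambdas:
        results = _results_for_lambda(state, lam, cfg.q_cut)
        drivers = results.index[results["is_driver"]]
        row: dict = {"lambda": lam, "n_drivers": len(drivers)}
        if panels:
            from .evaluation import overlap_fraction

            for name, panel in panels.items():
                row[f"overlap_{name}"] = overlap_fraction(drivers, panel)
        rows.append(row)
    return pd.DataFrame(rows)
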