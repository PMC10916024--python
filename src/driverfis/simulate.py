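"""Synthetic cohorts with known ground truth.

Two generators back the test pyramid:

* :func:`simulate_regression` emits a bare standardized design and response
  drawn from the background model y = X beta + eps, eps ~ N(0, sigma0^2) —
  the direct probe for parameter recovery.
* :func:`simulate_cohort` emits a full file set (MAF, FIS lookup table,
  external feature table, truth file) whose per-gene filled-FIS totals
  reproduce a response drawn from that same model: mutation counts and
  effect classes are allocated first, a latent per-gene FIS dispersion
  stands in for the yet-unknown sd-of-FIS covariate, y_g is drawn from the
  model, and per-mutation scores are shifted so each gene's total equals its
  draw. Optional spiked driver genes receive extra harmful mutations in
  distinct samples. Missingness in the feature table and FIS lookup is
  injected at configurable rates so every imputation/filling code path is
  reachable.

The generator makes no attempt to mimic mutational signatures,
trinucleotide context, or chromosomal clustering — positions are synthetic
bookkeeping keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .background import BackgroundModel
from .features import EXTERNAL_FEATURES, GeneFeatureMatrix
from .maf_io import Effect, FisTable, MutationRecord, write_maf

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "default_beta",
    "simulate_regression",
    "simulate_cohort",
    "worked_micro_example",
]

_CHROMS = [str(c) for c in range(1, 23)] + ["X"]

#: effect class -> (MAF classification written, base FIS mean, base FIS sd)
_EFFECT_PROFILE = {
    Effect.SILENT: ("Silent", 0.3, 0.3),
    Effect.NONSILENT: ("Missense_Mutation", 2.0, 0.8),
    Effect.NULL: ("Nonsense_Mutation", 3.0, 0.5),
    Effect.NONCODING: ("Intron", 1.0, 0.5),
}

_DEFAULT_MIXTURE = {
    Effect.SILENT: 0.25,
    Effect.NONSILENT: 0.55,
    Effect.NULL: 0.10,
    Effect.NONCODING: 0.10,
}


def default_beta(p_features: int = 12) -> np.ndarray:
    """Fixed true coefficient vector (intercept first) used by the generators.

    Externals carry modest mixed-sign effects; the mutation-count covariates
    carry the dominant positive effects, as they do in real cohorts where a
    gene's FIS total scales with its mutation burden.
    """
    base = [5.0, 0.5, -0.3, 0.2, 0.4, -0.2, 0.1, 0.3, -0.1, 0.2, 2.0, 1.0, 0.5]
    if p_features != 12:
        rng = np.random.default_rng(12)
        return np.concatenate([[5.0], rng.normal(0.0, 0.5, p_features)])
    return np.asarray(base)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``driver_effect`` is the total excess FIS spiked into each driver gene,
    delivered as extra harmful mutations of ``driver_mutation_fis`` each in
    distinct samples.
    """

    n_genes: int = 2000
    n_samples: int = 200
    p_features: int = 12
    beta_true: Optional[np.ndarray] = None
    sigma0_true: float = 2.0
    n_drivers: int = 0
    driver_effect: float = 70.0
    driver_mutation_fis: float = 3.5
    missing_feature_rate: float = 0.05
    missing_fis_rate: float = 0.3
    mean_mutations: float = 3.0
    effect_mixture: Mapping[Effect, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers > self.n_genes:
            raise ValueError("n_drivers cannot exceed n_genes")
        for r in (self.missing_feature_rate, self.missing_fis_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("missingness rates must lie in [0, 1)")
        if abs(sum(self.effect_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("effect mixture must sum to 1")
        if self.beta_true is not None and len(self.beta_true) != self.p_features + 1:
            raise ValueError("beta_true must have length p_features + 1")

    @property
    def beta(self) -> np.ndarray:
        return (
            np.asarray(self.beta_true, dtype=float)
            if self.beta_true is not None
            else default_beta(self.p_features)
        )


def simulate_regression(
    n_genes: int = 3000,
    p_features: int = 12,
    beta: Optional[np.ndarray] = None,
    sigma0: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (X, y, beta) directly from the background model.

    X is standard normal then column-standardized (n-1); y = [1, X] beta +
    N(0, sigma0^2). Returns the design, response and the true coefficient
    vector (intercept first).
    """
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = default_beta(p_features)
    beta = np.asarray(beta, dtype=float)
    X = rng.standard_normal((n_genes, p_features))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    y = beta[0] + X @ beta[1:] + rng.normal(0.0, sigma0, n_genes)
    return X, y, beta


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort plus its generating truth."""

    records: list[MutationRecord]
    fis_table: FisTable
    external_features: GeneFeatureMatrix
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the cohort in the same dialects the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / "cohort.maf",
            "fis_table": outdir / "fis_table.tsv",
            "features": outdir / "features.tsv",
            "truth": outdir / "truth.json",
        }
        write_maf(self.records, paths["maf"])
        rows = [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "score": s}
            for (c, p, r, a), s in sorted(self.fis_table.scores.items())
        ]
        pd.DataFrame(rows).to_csv(paths["fis_table"], sep="\t", index=False)
        self.external_features.to_frame().rename_axis("gene").to_csv(
            paths["features"], sep="\t"
        )
        paths["truth"].write_text(json.dumps(self.truth, indent=2))
        return paths


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under the background model."""
    rng = np.random.default_rng(cfg.seed)
    n, M = cfg.n_genes, cfg.n_samples
    genes = [f"GENE{i + 1:05d}" for i in range(n)]
    samples = [f"SAMPLE{j + 1:04d}" for j in range(M)]
    beta = cfg.beta
    n_ext = cfg.p_features - 3
    ext_names = list(EXTERNAL_FEATURES[:n_ext]) + [
        f"extra_{i}" for i in range(max(0, n_ext - len(EXTERNAL_FEATURES)))
    ]

    effects_pool = list(cfg.effect_mixture.keys())
    probs = np.array([cfg.effect_mixture[e] for e in effects_pool])

    # per-gene mutation allocation (counts, effects, samples)
    m_g = 1 + rng.poisson(max(cfg.mean_mutations - 1.0, 0.0), n)
    gene_effects = [
        [effects_pool[k] for k in rng.choice(len(effects_pool), m, p=probs)]
        for m in m_g
    ]
    gene_samples = [list(rng.integers(0, M, m)) for m in m_g]

    # latent design: externals, counts, and a latent FIS-dispersion column
    ext = rng.standard_normal((n, n_ext))
    h_g = np.array([sum(e.is_harmful for e in ge) for ge in gene_effects])
    s_lat = np.abs(rng.standard_normal(n))
    design_raw = np.column_stack([ext, m_g.astype(float), h_g.astype(float), s_lat])
    design = (design_raw - design_raw.mean(axis=0)) / design_raw.std(axis=0, ddof=1)
    y_g = beta[0] + design @ beta[1:] + rng.normal(0.0, cfg.sigma0_true, n)

    # spiked drivers: extra harmful mutations in distinct samples
    driver_idx = sorted(rng.choice(n, cfg.n_drivers, replace=False).tolist())
    n_extra = int(round(cfg.driver_effect / cfg.driver_mutation_fis))
    if cfg.n_drivers and (n_extra < 1 or n_extra > M):
        raise ValueError(
            f"infeasible driver allocation: {n_extra} extra mutations per "
            f"driver vs {M} samples"
        )

    records: list[MutationRecord] = []
    table: dict[tuple[str, int, str, str], float] = {}
    nucs = np.array(list("ACGT"))

    def emit(gene_i: int, counter: int, sample_j: int, effect: Effect, fis: float) -> int:
        chrom = _CHROMS[gene_i % len(_CHROMS)]
        pos = (gene_i // len(_CHROMS) + 1) * 1_000_000 + counter
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        classification = _EFFECT_PROFILE[effect][0]
        records.append(
            MutationRecord(
                sample_id=samples[sample_j],
                gene=genes[gene_i],
                chrom=chrom,
                start_pos=pos,
                end_pos=pos,
                ref_allele=str(nucs[ref_i]),
                alt_allele=str(nucs[alt_i]),
                variant_classification=classification,
            )
        )
        if rng.random() >= cfg.missing_fis_rate:
            table[(chrom, pos, str(nucs[ref_i]), str(nucs[alt_i]))] = round(fis, 4)
        return counter + 1

    for i in range(n):
        base = np.array(
            [rng.normal(*_EFFECT_PROFILE[e][1:]) for e in gene_effects[i]]
        )
        fis_i = base + (y_g[i] - base.sum()) / m_g[i]  # totals match the draw
        counter = 0
        for e, sj, f in zip(gene_effects[i], gene_samples[i], fis_i):
            counter = emit(i, counter, sj, e, f)
        if i in driver_idx:
            extra_samples = rng.choice(M, n_extra, replace=False)
            for sj in extra_samples:
                counter = emit(
                    i, counter, int(sj), Effect.NONSILENT, cfg.driver_mutation_fis
                )

    # external feature table with injected missingness
    ext_values = ext.copy()
    if cfg.missing_feature_rate > 0:
        mask = rng.random(ext_values.shape) < cfg.missing_feature_rate
        ext_values[mask] = np.nan
    external = GeneFeatureMatrix(
        genes=genes, feature_names=ext_names, values=np.round(ext_values, 6)
    )

    truth = {
        "drivers": [genes[i] for i in driver_idx],
        "beta_true": beta.tolist(),
        "sigma0_true": cfg.sigma0_true,
        "n_genes": n,
        "n_samples": M,
        "seed": cfg.seed,
    }
    return SimulatedCohort(
        records=records,
        fis_table=FisTable(table),
        external_features=external,
        truth=truth,
    )


def worked_micro_example() -> dict:
    """A hand-checkable 6-gene, 4-sample cohort with expected intermediates.

    Every mutation carries an explicit FIS and effect, so the per-gene
    observed totals, ratiometric weights and weighted scores below can be
    verified with pencil and paper; a preset intercept-only background model
    (mean 2, sd 1) makes the p-values checkable too.
    """
    e = np.e
    S = [f"S{i}" for i in range(1, 5)]

    def rec(gene, sample, effect, fis, pos):
        return MutationRecord(
            sample_id=sample, gene=gene, chrom="1", start_pos=pos, end_pos=pos,
            ref_allele="A", alt_allele="G",
            variant_classification=_EFFECT_PROFILE[effect][0],
            effect=effect, fis=fis,
        )

    records = [
        rec("ALPHA", S[0], Effect.NONSILENT, 2.0, 101),
        rec("ALPHA", S[1], Effect.NONSILENT, 2.0, 102),
        rec("ALPHA", S[0], Effect.SILENT, 0.0, 103),
        rec("ALPHA", S[1], Effect.SILENT, 0.0, 104),
        rec("BRAVO", S[0], Effect.SILENT, 0.5, 201),
        rec("BRAVO", S[1], Effect.SILENT, 0.3, 202),
        rec("CHARLIE", S[0], Effect.NULL, 3.0, 301),
        rec("CHARLIE", S[0], Effect.NULL, 3.5, 302),
        rec("DELTA", S[2], Effect.NONSILENT, 1.0, 401),
        rec("ECHO", S[3], Effect.NONCODING, 1.2, 501),
        rec("ECHO", S[2], Effect.SILENT, 0.0, 502),
        rec("FOXTROT", S[0], Effect.NONSILENT, 2.2, 601),
        rec("FOXTROT", S[1], Effect.NONSILENT, 1.8, 602),
        rec("FOXTROT", S[2], Effect.NULL, 3.0, 603),
        rec("FOXTROT", S[3], Effect.NULL, 2.0, 604),
    ]

    expected = {
        "ALPHA": dict(y_obs=4.0, m_total=4, m_harm_mut=2, m_harm_samples=2,
                      w1=0.5, w2=e ** 0.5, y_w=2 * e ** 0.5),
        "BRAVO": dict(y_obs=0.8, m_total=2, m_harm_mut=0, m_harm_samples=0,
                      w1=0.0, w2=1.0, y_w=0.0),
        "CHARLIE": dict(y_obs=6.5, m_total=2, m_harm_mut=2, m_harm_samples=1,
                        w1=1.0, w2=e ** 0.25, y_w=6.5 * e ** 0.25),
        "DELTA": dict(y_obs=1.0, m_total=1, m_harm_mut=1, m_harm_samples=1,
                      w1=1.0, w2=e ** 0.25, y_w=e ** 0.25),
        "ECHO": dict(y_obs=1.2, m_total=2, m_harm_mut=0, m_harm_samples=0,
                     w1=0.0, w2=1.0, y_w=0.0),
        "FOXTROT": dict(y_obs=9.0, m_total=4, m_harm_mut=4, m_harm_samples=4,
                        w1=1.0, w2=e, y_w=9.0 * e),
    }
    background = BackgroundModel(
        beta=np.array([2.0]), sigma0=1.0, feature_names=(), n_fit=6
    )
    return {"records": records, "M": 4, "expected": expected,
            "background": background}
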