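"""Double-weighted driver-gene testing with BH FDR control.

Each gene's observed FIS total is re-weighted by two ratiometric factors —
w1, the fraction of its mutations that are harmful, and w2, the exponential
of the fraction of cohort samples carrying a harmful mutation in it — and
the weighted score is tested upper-tail against a normal null centred at the
gene's (shrunken) background score with the model's residual sd. Genes with
no harmful mutation receive p = 1 outright. Benjamini-Hochberg q-values
at q <= 0.05 define the driver calls.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "weight_harm_fraction",
    "weight_harm_prevalence",
    "weighted_fis",
    "gene_pvalue",
    "bh_adjust",
    "call_drivers",
    "score_genes",
]


def weight_harm_fraction(m_harm_mut: int, m_total: int) -> float:
    """w1 = harmful mutations / total mutations, in [0, 1]."""
    if m_total < 1:
        raise ValueError("gene has no mutations; it should not be under test")
    if not 0 <= m_harm_mut <= m_total:
        raise ValueError("m_harm_mut must lie in [0, m_total]")
    return m_harm_mut / m_total


def weight_harm_prevalence(m_harm_samples: int, M: int) -> float:
    """w2 = exp(harmful samples / cohort size), in [1, e]."""
    if M < 1:
        raise ValueError("cohort size M must be >= 1")
    if not 0 <= m_harm_samples <= M:
        raise ValueError("m_harm_samples must lie in [0, M]")
    return math.exp(m_harm_samples / M)


def weighted_fis(w1: float, w2: float, y_obs: float) -> float:
    """Weighted observed FIS y_w = w1 * w2 * y_obs."""
    return w1 * w2 * y_obs


def gene_pvalue(y_w: float, y_fb: float, sigma0: float, m_harm_mut: int) -> float:
    """Upper-tail p-value of the weighted score under N(y_fb, sigma0^2).

    A gene with zero harmful mutations is assigned p = 1 without testing.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if m_harm_mut == 0:
        return 1.0
    return float(norm.sf((y_w - y_fb) / sigma0))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_drivers(results: pd.DataFrame, q_cut: float = 0.05) -> pd.DataFrame:
    """Flag drivers at q <= q_cut; sort by (q, p, gene symbol).

    ``results`` must be gene-indexed with ``p_value`` and ``q_value``
    columns; returns a sorted copy with an ``is_driver`` column.
    """
    out = results.copy()
    out["is_driver"] = out["q_value"] <= q_cut
    # stable sort: gene symbol (index) breaks (q, p) ties deterministically
    out = out.sort_index(kind="mergesort")
    return out.sort_values(["q_value", "p_value"], kind="mergesort")


def score_genes(
    summaries: pd.DataFrame,
    y_fb: pd.Series,
    sigma0: float,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Score, test and call every gene.

    ``summaries`` is the gene-indexed output of
    :func:`driverfis.observed.summarize_cohort`; ``y_fb`` the gene-indexed
    final background scores. Returns a DataFrame sorted by (q, p, gene)
    with w1, w2, y_w, y_fb, p_value, q_value, is_driver.
    """
    genes = summaries.index
    y_fb = y_fb.reindex(genes)
    if y_fb.isna().any():
        missing = list(y_fb[y_fb.isna()].index[:5])
        raise ValueError(f"no background score for gene(s) {missing}")
    w1 = np.array([
        weight_harm_fraction(int(r.m_harm_mut), int(r.m_total))
        for r in summaries.itertuples()
    ])
    w2 = np.array([
        weight_harm_prevalence(int(r.m_harm_samples), int(r.M))
        for r in summaries.itertuples()
    ])
    y_w = w1 * w2 * summaries["y_obs"].to_numpy()
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    # vectorized gene_pvalue: ndtr(-z) is exactly norm.sf(z)
    from scipy.special import ndtr

    z = (y_w - y_fb.to_numpy()) / sigma0
    p = np.where(summaries["m_harm_mut"].to_numpy() == 0, 1.0, ndtr(-z))
    q = bh_adjust(p)
    out = summaries.copy()
    out["w1"], out["w2"], out["y_w"] = w1, w2, y_w
    out["y_fb"] = y_fb
    out["p_value"], out["q_value"] = p, q
    return call_drivers(out, q_cut=q_cut)
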