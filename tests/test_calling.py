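"""Ratiometric weights, normal-null p-values, BH adjustment, driver calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverfis import (
    bh_adjust,
    call_drivers,
    gene_pvalue,
    score_genes,
    weight_harm_fraction,
    weight_harm_prevalence,
    weighted_fis,
)


class TestWeights:
    @pytest.mark.parametrize(
        "harm,total,expected", [(3, 4, 0.75), (4, 4, 1.0), (0, 4, 0.0)]
    )
    def test_harm_fraction(self, harm, total, expected):
        assert weight_harm_fraction(harm, total) == expected

    def test_harm_fraction_rejects_unmutated_gene(self):
        with pytest.raises(ValueError):
            weight_harm_fraction(0, 0)

    @pytest.mark.parametrize(
        "harm_samples,M,expected",
        [(0, 10, 1.0), (200, 200, math.e), (100, 200, math.exp(0.5))],
    )
    def test_harm_prevalence(self, harm_samples, M, expected):
        assert weight_harm_prevalence(harm_samples, M) == pytest.approx(expected)

    @settings(deadline=None, max_examples=10000)
    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(1, 1000))
    def test_weight_ranges_fuzzed(self, harm, total, M):
        total = max(total, harm, 1)
        harm_samples = min(harm, M)
        w1 = weight_harm_fraction(harm, total)
        w2 = weight_harm_prevalence(harm_samples, M)
        assert 0.0 <= w1 <= 1.0
        assert 1.0 <= w2 <= math.e
        assert 0.0 <= w1 * w2 <= math.e

    @pytest.mark.parametrize(
        "w1,w2,y,expected", [(0.5, 2.0, 10.0, 10.0), (0.0, 2.0, 7.0, 0.0),
                             (1.0, 1.0, 3.3, 3.3)]
    )
    def test_weighted_fis(self, w1, w2, y, expected):
        assert weighted_fis(w1, w2, y) == expected


class TestPValue:
    def test_null_median(self):
        assert gene_pvalue(5.0, 5.0, 1.0, m_harm_mut=3) == pytest.approx(0.5)

    def test_zero_harm_gives_one(self):
        assert gene_pvalue(100.0, 0.0, 1.0, m_harm_mut=0) == 1.0

    def test_standard_normal_quantile(self):
        p = gene_pvalue(1.644854, 0.0, 1.0, m_harm_mut=1)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gene_pvalue(1.0, 0.0, 0.0, m_harm_mut=1)

    def test_strictly_decreasing_in_y_w(self):
        ps = [gene_pvalue(y, 2.0, 1.5, 1) for y in np.linspace(-5, 5, 50)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


def _naive_bh(p):
    """Step-up definition applied literally."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBH:
    def test_all_null(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_matches_naive_step_up(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            np.testing.assert_allclose(bh_adjust(p), _naive_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominance_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDrivers:
    def _results(self, p):
        q = bh_adjust(p)
        return pd.DataFrame(
            {"p_value": p, "q_value": q},
            index=[f"G{i}" for i in range(len(p))],
        )

    def test_global_null_calls_nothing(self):
        out = call_drivers(self._results([1.0, 1.0, 1.0]))
        assert not out["is_driver"].any()

    def test_boundary_inclusive(self):
        df = pd.DataFrame(
            {"p_value": [0.01, 0.05, 0.051], "q_value": [0.01, 0.05, 0.051]},
            index=["A", "B", "C"],
        )
        out = call_drivers(df, q_cut=0.05)
        assert out["is_driver"].sum() == 2

    def test_order_invariance(self, rng):
        p = rng.random(20)
        df = self._results(p)
        out1 = call_drivers(df)
        out2 = call_drivers(df.sample(frac=1, random_state=1))
        assert set(out1.index[out1.is_driver]) == set(out2.index[out2.is_driver])


def test_test_genes_micro_cohort(micro):
    from driverfis import Effect, summarize_cohort

    usable = [r for r in micro["records"] if r.effect is not Effect.IGNORE]
    summaries = summarize_cohort(usable, M=micro["M"])
    bg = micro["background"]
    y_fb = pd.Series(bg.beta[0], index=summaries.index)
    out = score_genes(summaries, y_fb, bg.sigma0)
    for gene, exp in micro["expected"].items():
        assert out.loc[gene, "w1"] == pytest.approx(exp["w1"])
        assert out.loc[gene, "w2"] == pytest.approx(exp["w2"])
        assert out.loc[gene, "y_w"] == pytest.approx(exp["y_w"])
    # zero-harm genes receive p = 1 outright
    assert out.loc["BRAVO", "p_value"] == 1.0
    assert out.loc["ECHO", "p_value"] == 1.0
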