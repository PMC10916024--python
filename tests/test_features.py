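"""Covariate assembly, KNN imputation, and standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverfis import (
    Effect,
    GeneFeatureMatrix,
    MutationRecord,
    compute_maf_features,
    euclidean_distance,
    impute_missing,
    standardize,
)


def _rec(gene, sample, effect, fis):
    return MutationRecord(
        sample_id=sample, gene=gene, chrom="1", start_pos=1, end_pos=1,
        ref_allele="A", alt_allele="G", variant_classification="x",
        effect=effect, fis=fis,
    )


class TestMafFeatures:
    def test_counts_by_effect_class(self):
        recs = [
            _rec("G1", "S1", Effect.SILENT, 0.0),
            _rec("G1", "S2", Effect.NONSILENT, 2.0),
            _rec("G1", "S3", Effect.NULL, 3.0),
        ]
        out = compute_maf_features(recs)
        assert out.loc["G1", "total_mutations"] == 3
        assert out.loc["G1", "harmful_mutations"] == 2

    def test_single_patient_gene_has_zero_fis_sd(self):
        recs = [_rec("G1", "S1", Effect.NONSILENT, 2.0),
                _rec("G1", "S1", Effect.NONSILENT, 1.0)]
        assert compute_maf_features(recs).loc["G1", "fis_sd"] == 0.0

    def test_two_patient_sd_is_sample_sd(self):
        # per-patient totals {1.0, 3.0} -> sd with n-1 is sqrt(2)
        recs = [_rec("G1", "S1", Effect.NONSILENT, 1.0),
                _rec("G1", "S2", Effect.NONSILENT, 3.0)]
        assert compute_maf_features(recs).loc["G1", "fis_sd"] == pytest.approx(
            np.sqrt(2.0)
        )

    def test_ignored_records_excluded(self):
        recs = [_rec("G1", "S1", Effect.NONSILENT, 2.0),
                _rec("G1", "S2", Effect.IGNORE, None)]
        assert compute_maf_features(recs).loc["G1", "total_mutations"] == 1

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            compute_maf_features([])


class TestDistance:
    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0

    def test_exclusion(self):
        assert euclidean_distance([1, 2, 9], [1, 5, 0], exclude=2) == 3.0

    def test_missing_coordinates_skipped(self):
        assert euclidean_distance([1.0, np.nan, 4.0], [1.0, 2.0, 1.0]) == 3.0

    def test_all_missing_error(self):
        with pytest.raises(ValueError):
            euclidean_distance([np.nan, 1.0], [2.0, np.nan])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8))
    def test_symmetry_and_identity(self, v):
        w = list(reversed(v))
        assert euclidean_distance(v, v) == 0.0
        assert euclidean_distance(v, w) == pytest.approx(
            euclidean_distance(w, v)
        )


def _brute_force_impute(values, genes, K):
    """Independent oracle: plain loops straight from the definitions."""
    obs_mean = np.nanmean(values, axis=0)
    obs_sd = np.nanstd(values, axis=0, ddof=1)
    scaled = (values - obs_mean) / np.where(obs_sd == 0, 1, obs_sd)
    out = values.copy()
    n, p = values.shape
    for g in range(n):
        for k in range(p):
            if not np.isnan(values[g, k]):
                continue
            cands = []
            for j in range(n):
                if np.isnan(values[j, k]):
                    continue
                d2, used = 0.0, 0
                for l in range(p):
                    if l == k:
                        continue
                    if np.isnan(scaled[g, l]) or np.isnan(scaled[j, l]):
                        continue
                    d2 += (scaled[g, l] - scaled[j, l]) ** 2
                    used += 1
                if used:
                    cands.append((np.sqrt(d2), genes[j], j))
            cands.sort()
            chosen = [j for _, _, j in cands[:K]]
            out[g, k] = np.mean([values[j, k] for j in chosen])
    return out


class TestImpute:
    def test_constant_neighborhood(self, rng):
        values = np.full((12, 3), 2.5)
        values += rng.normal(0, 1e-9, values.shape)  # break distance ties
        values[:, 1] = rng.normal(0, 1, 12)
        values[0, 0] = np.nan
        m = GeneFeatureMatrix([f"G{i}" for i in range(12)], list("abc"), values)
        out = impute_missing(m, K=5)
        assert out.values[0, 0] == pytest.approx(2.5, abs=1e-6)

    def test_fully_observed_is_noop(self, rng):
        values = rng.normal(size=(10, 4))
        m = GeneFeatureMatrix([f"G{i}" for i in range(10)], list("abcd"), values)
        np.testing.assert_array_equal(impute_missing(m, K=3).values, values)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(30, 5))
        miss = rng.choice(30 * 5, size=10, replace=False)
        values.ravel()[miss] = np.nan
        genes = [f"G{i:02d}" for i in range(30)]
        m = GeneFeatureMatrix(genes, list("abcde"), values.copy())
        expected = _brute_force_impute(values.copy(), genes, K=5)
        np.testing.assert_allclose(
            impute_missing(m, K=5).values, expected, atol=1e-12
        )

    def test_imputed_within_observed_range(self, rng):
        values = rng.normal(size=(40, 4))
        mask = rng.random(values.shape) < 0.15
        values[mask] = np.nan
        m = GeneFeatureMatrix([f"G{i}" for i in range(40)], list("abcd"), values)
        out = impute_missing(m, K=7)
        for k in range(4):
            obs = values[~np.isnan(values[:, k]), k]
            imp = out.values[np.isnan(values[:, k]), k]
            assert np.all(imp >= obs.min()) and np.all(imp <= obs.max())

    def test_permutation_equivariance(self, rng):
        values = rng.normal(size=(25, 4))
        mask = rng.random(values.shape) < 0.1
        values[mask] = np.nan
        genes = [f"G{i:02d}" for i in range(25)]
        m = GeneFeatureMatrix(genes, list("abcd"), values.copy())
        out = impute_missing(m, K=5)
        perm = rng.permutation(25)
        mp = GeneFeatureMatrix(
            [genes[i] for i in perm], list("abcd"), values[perm].copy()
        )
        outp = impute_missing(mp, K=5)
        np.testing.assert_allclose(outp.values, out.values[perm], atol=1e-12)

    def test_feature_missing_everywhere_errors(self):
        values = np.ones((5, 2))
        values[:, 1] = np.nan
        values[:, 0] = np.arange(5.0)
        m = GeneFeatureMatrix([f"G{i}" for i in range(5)], ["a", "b"], values)
        with pytest.raises(ValueError, match="b"):
            impute_missing(m, K=2)


class TestStandardize:
    def test_symmetric_three_point(self):
        m = GeneFeatureMatrix(["a", "b", "c"], ["f"], [[1.0], [2.0], [3.0]])
        np.testing.assert_allclose(
            standardize(m).values.ravel(), [-1.0, 0.0, 1.0]
        )

    def test_idempotent(self, rng):
        m = GeneFeatureMatrix(
            [f"G{i}" for i in range(20)], list("ab"), rng.normal(size=(20, 2))
        )
        once = standardize(m)
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_column_moments(self, rng):
        m = GeneFeatureMatrix(
            [f"G{i}" for i in range(50)], list("abc"), rng.normal(2, 5, (50, 3))
        )
        out = standardize(m)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_constant_column_errors(self):
        m = GeneFeatureMatrix(["a", "b"], ["f", "g"], [[1.0, 1.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="g"):
            standardize(m)

    def test_missing_entries_rejected(self):
        m = GeneFeatureMatrix(["a", "b"], ["f"], [[1.0], [np.nan]])
        with pytest.raises(ValueError, match="impute"):
            standardize(m)
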