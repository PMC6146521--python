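import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metlink.errors import DataError, NormalizationError, UsageError
from metlink.expression_quant import (
    CountMatrix,
    bh_adjust,
    compute_size_factors,
    pair_fold_change,
    pca_outlier_flags,
    term_overrepresentation,
)


def cm(data, genes=None, samples=None, **kw):
    genes = genes or [f"g{i}" for i in range(1, len(data) + 1)]
    samples = samples or [f"s{i}" for i in range(1, len(data[0]) + 1)]
    return CountMatrix(counts=pd.DataFrame(data, index=genes, columns=samples), **kw)


class TestSizeFactors:
    def test_identical_columns(self):
        f = compute_size_factors(cm([[10, 10], [30, 30], [5, 5]]))
        assert list(f) == pytest.approx([1.0, 1.0])

    def test_hand_example(self):
        f = compute_size_factors(cm([[10, 20], [30, 60]]))
        assert list(f) == pytest.approx([1 / math.sqrt(2), math.sqrt(2)], abs=1e-12)

    def test_scale_equivariance(self):
        base = cm([[10, 20], [30, 60], [7, 9]])
        scaled = cm([[10, 60], [30, 180], [7, 27]])
        f0 = compute_size_factors(base)
        f1 = compute_size_factors(scaled)
        # scaling one column by k moves the per-gene geometric means too, so the
        # equivariance is exact on factor ratios
        assert (f1["s2"] / f1["s1"]) == pytest.approx(3 * f0["s2"] / f0["s1"], rel=1e-12)

    def test_zero_gene_everywhere_error(self):
        with pytest.raises(NormalizationError):
            compute_size_factors(cm([[0, 5], [3, 0]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError):
            cm([[1, 2], [3, 4]], genes=["g1", "g1"])

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            cm([[1, -2], [3, 4]])


class TestPairFoldChange:
    def test_identical_columns_fc_one(self):
        norm = cm([[10, 10], [3, 3], [7, 7]], samples=["t", "n"], size_factors=pd.Series({"t": 1.0, "n": 1.0}))
        r = pair_fold_change(norm, "t", "n")
        assert list(r.table["fc"]) == pytest.approx([1.0, 1.0, 1.0])

    def test_double_zero_gene_dropped(self):
        norm = cm([[10, 5], [0, 0]], samples=["t", "n"], size_factors=pd.Series({"t": 1.0, "n": 1.0}))
        r = pair_fold_change(norm, "t", "n")
        assert "g2" not in r.table.index
        assert r.dropped_genes == ["g2"]

    def test_five_gene_hand_computation(self):
        norm = cm(
            [[20, 10], [5, 10], [0, 4], [9, 0], [3, 3]],
            genes=list("abcde"),
            samples=["t", "n"],
            size_factors=pd.Series({"t": 1.0, "n": 1.0}),
        )
        r = pair_fold_change(norm, "t", "n", pseudocount=0.5)
        expect = {
            "a": 20.5 / 10.5,
            "b": 5.5 / 10.5,
            "c": 0.5 / 4.5,
            "d": 9.5 / 0.5,
            "e": 3.5 / 3.5,
        }
        assert r.table["fc"].to_dict() == pytest.approx(expect)
        # descending FC: d (19.0), a (1.952), e (1.0), b (0.524), c (0.111)
        assert list(r.table.index) == ["d", "a", "e", "b", "c"]
        assert list(r.table["rank"]) == [1, 2, 3, 4, 5]

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 50, size=(30, 2))
        norm = cm(data.tolist(), samples=["t", "n"], size_factors=pd.Series({"t": 1.0, "n": 1.0}))
        r = pair_fold_change(norm, "t", "n")
        assert sorted(r.table["rank"]) == list(range(1, r.n_genes + 1))

    def test_tie_break_lexicographic(self):
        norm = cm([[5, 5], [5, 5]], genes=["zz", "aa"], samples=["t", "n"],
                  size_factors=pd.Series({"t": 1.0, "n": 1.0}))
        r = pair_fold_change(norm, "t", "n")
        assert list(r.table.index) == ["aa", "zz"]

    def test_cross_patient_pairing_rejected(self, toy_counts, toy_sample_sheet):
        norm = CountMatrix(counts=toy_counts).normalized()
        with pytest.raises(UsageError, match="different patients"):
            pair_fold_change(norm, "P01.MT", "P02.N", sample_sheet=toy_sample_sheet)

    def test_fc_invariant_to_common_scaling(self, toy_counts):
        m1 = CountMatrix(counts=toy_counts).normalized()
        m2 = CountMatrix(counts=toy_counts * 7).normalized()
        r1 = pair_fold_change(m1, "P01.MT", "P01.N")
        r2 = pair_fold_change(m2, "P01.MT", "P01.N")
        # size factors absorb the common constant; rank order identical
        assert list(r1.table.index) == list(r2.table.index)


def reference_bh(p):
    """Step-up formula, written independently of the implementation."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        val = min(prev, p[i] * n / (rank_pos + 1))
        adj[i] = val
        prev = val
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_hand_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4, abs=1e-15)

    def test_all_ones(self):
        assert list(bh_adjust([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.max(np.abs(bh_adjust(p) - np.array(reference_bh(list(p))))) < 1e-12

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(0, 1, size=25)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(bh_adjust(p) - ref)) < 1e-12


class TestPcaOutliers:
    def base_matrix(self, n_genes=60, n_samples=6, seed=0):
        rng = np.random.default_rng(seed)
        means = rng.uniform(20, 200, size=n_genes)
        data = rng.poisson(means[:, None], size=(n_genes, n_samples))
        return data.astype(float)

    def test_identical_columns_no_flags(self):
        data = np.tile(np.arange(1, 21)[:, None], (1, 5)).astype(float)
        m = cm(data.tolist(), genes=[f"g{i}" for i in range(20)], samples=list("abcde"))
        assert pca_outlier_flags(m, n_components=2, z_threshold=3.0) == []

    def test_scaled_column_flagged_on_normalized_input(self):
        # matrix declared already-normalized: a 100x column is a true outlier
        data = self.base_matrix()
        data[:, 2] *= 100
        m = cm(data.tolist(), genes=[f"g{i}" for i in range(60)],
               samples=list("abcdef"), size_factors=pd.Series(1.0, index=list("abcdef")))
        assert pca_outlier_flags(m, n_components=3, z_threshold=3.0) == ["c"]

    def test_global_scaling_of_raw_column_absorbed(self):
        # on raw counts, median-of-ratios normalization removes a pure library-size
        # effect, so the scaled sample is NOT an expression outlier
        data = self.base_matrix(n_genes=200)
        data[:, 2] *= 100
        m = cm(data.tolist(), genes=[f"g{i}" for i in range(200)], samples=list("abcdef"))
        assert "c" not in pca_outlier_flags(m, n_components=3, z_threshold=4.0)

    def test_infinite_threshold_never_flags(self):
        data = self.base_matrix()
        data[:, 0] *= 50
        m = cm(data.tolist(), genes=[f"g{i}" for i in range(60)], samples=list("abcdef"),
               size_factors=pd.Series(1.0, index=list("abcdef")))
        assert pca_outlier_flags(m, n_components=3, z_threshold=math.inf) == []

    def test_usage_errors(self):
        data = self.base_matrix(n_samples=4)
        m = cm(data.tolist(), genes=[f"g{i}" for i in range(60)], samples=list("abcd"))
        with pytest.raises(UsageError):
            pca_outlier_flags(m, n_components=4)
        tiny = cm([[1, 2], [3, 4]])
        with pytest.raises(UsageError):
            pca_outlier_flags(tiny, n_components=1)


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P(X >= k), X ~ Hypergeometric(N, K, n), by explicit summation."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestTermOverrepresentation:
    def setup_method(self):
        self.universe = [f"g{i}" for i in range(100)]

    def test_enclosed_term_matches_hypergeometric_oracle(self):
        selected = self.universe[:10]
        term_map = {"T1": self.universe[:5]}
        # |term|=5 < 2% of 100 would exclude it; relax the cap to test the p-value
        df = term_overrepresentation(selected, self.universe, term_map, min_term=3, max_term_frac=0.5)
        oracle = hypergeom_tail_by_enumeration(100, 5, 10, 5)
        assert df.loc[0, "p_value"] == pytest.approx(oracle, rel=1e-12)
        assert df.loc[0, "count"] == 5
        assert df.loc[0, "expected_count"] == pytest.approx(5 * 10 / 100)

    def test_disjoint_term_not_enriched(self):
        selected = self.universe[:5]
        term_map = {"T1": self.universe[50:60]}
        df = term_overrepresentation(selected, self.universe, term_map, max_term_frac=0.5)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_small_term_excluded(self):
        df = term_overrepresentation(
            self.universe[:10], self.universe, {"tiny": self.universe[:2]}, min_term=3, max_term_frac=0.5
        )
        assert len(df) == 0

    def test_large_term_excluded_by_frac(self):
        df = term_overrepresentation(
            self.universe[:10], self.universe, {"big": self.universe[:3]}, min_term=3, max_term_frac=0.02
        )
        assert len(df) == 0  # size 3 >= 0.02 * 100

    def test_empty_universe_is_usage_error(self):
        with pytest.raises(UsageError):
            term_overrepresentation([], [], {"T": ["g"]})

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(UsageError):
            term_overrepresentation(["nope"], self.universe, {})

    @given(st.integers(0, 10), st.integers(1, 30))
    @settings(max_examples=30, deadline=None)
    def test_random_terms_match_oracle(self, overlap, extra):
        rng = np.random.default_rng(overlap * 100 + extra)
        selected = self.universe[:20]
        k = min(overlap, 20)
        members = selected[:k] + self.universe[20 : 20 + extra]
        df = term_overrepresentation(selected, self.universe, {"T": members}, min_term=1, max_term_frac=1.0)
        if len(df) == 0:
            return
        oracle = hypergeom_tail_by_enumeration(100, len(members), 20, df.loc[0, "count"])
        assert df.loc[0, "p_value"] == pytest.approx(oracle, rel=1e-9)
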