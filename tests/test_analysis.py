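"""Downstream analyses driven by per-sample scores."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemsc import (
    ExpressionDataset,
    StemSCScore,
    classify_stem_like,
    compare_groups,
    hypergeometric_enrichment,
    preranked_enrichment,
    rank_genes_by_score_correlation,
    select_hvg,
    select_root_state,
    select_stem_threshold,
)


def scores_from(values, samples=None):
    samples = samples or [f"s{j}" for j in range(len(values))]
    out = []
    for sample, v in zip(samples, values):
        if v is None:
            out.append(StemSCScore(sample, 0, 0, math.nan, True))
        else:
            out.append(StemSCScore(sample, 100, int(round(v * 100)), v, False))
    return out


# ---------------------------------------------------------------------------
# rank_genes_by_score_correlation


class TestRankGenes:
    def _dataset(self, matrix, samples):
        genes = [f"g{i}" for i in range(len(matrix))]
        return ExpressionDataset.from_arrays("d", matrix, genes, samples)

    def test_perfectly_correlated_gene_first(self):
        svals = [0.1, 0.4, 0.6, 0.9]
        ds = self._dataset(
            [svals, [9, 6, 4, 1], [5, 5, 5, 5]], [f"s{j}" for j in range(4)]
        )
        table = rank_genes_by_score_correlation(ds, scores_from(svals))
        assert table.iloc[0]["gene"] == "g0" and table.iloc[0]["rho"] == pytest.approx(1.0)
        assert table.iloc[1]["gene"] == "g1" and table.iloc[1]["rho"] == pytest.approx(-1.0)
        assert table.iloc[2]["gene"] == "g2" and np.isnan(table.iloc[2]["rho"])

    def test_matches_per_gene_loop(self, rng):
        svals = rng.random(10).tolist()
        X = rng.lognormal(size=(12, 10))
        ds = self._dataset(X, [f"s{j}" for j in range(10)])
        table = rank_genes_by_score_correlation(ds, scores_from(svals)).set_index("gene")
        for i in range(12):
            ref = stats.spearmanr(X[i], svals)
            assert table.loc[f"g{i}", "rho"] == pytest.approx(ref.statistic, abs=1e-12)

    def test_misaligned_samples_rejected(self, rng):
        ds = self._dataset(rng.random((3, 4)), ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="aligned"):
            rank_genes_by_score_correlation(ds, scores_from([0.1, 0.2, 0.3, 0.4]))

    def test_needs_four_defined_scores(self, rng):
        ds = self._dataset(rng.random((3, 4)), [f"s{j}" for j in range(4)])
        with pytest.raises(ValueError, match="defined"):
            rank_genes_by_score_correlation(ds, scores_from([0.1, 0.2, 0.3, None]))


# ---------------------------------------------------------------------------
# preranked_enrichment


class TestPrerankedEnrichment:
    def test_hand_computed_running_sum(self):
        stats_map = {"g1": 3.0, "g2": 2.0, "g3": 1.0, "g4": -1.0, "g5": -2.0}
        res = preranked_enrichment(stats_map, ["g1", "g2"], n_perm=100, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_bottom_set_negative(self):
        stats_map = {f"g{i}": 10.0 - i for i in range(20)}
        res = preranked_enrichment(stats_map, ["g18", "g19"], n_perm=100, seed=0)
        assert res.es < 0

    def test_full_universe_es_zero(self):
        stats_map = {f"g{i}": float(i) for i in range(10)}
        res = preranked_enrichment(stats_map, list(stats_map), n_perm=100, seed=0)
        assert res.es == 0.0 and res.p == 1.0

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            preranked_enrichment({"g1": 1.0}, ["zz"], n_perm=100, seed=0)

    def test_nperm_floor(self):
        with pytest.raises(ValueError, match="n_perm"):
            preranked_enrichment({"g1": 1.0, "g2": 0.5}, ["g1"], n_perm=10, seed=0)

    def test_p_bounds(self, rng):
        stats_map = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        res = preranked_enrichment(stats_map, [f"g{i}" for i in range(5)], n_perm=200, seed=1)
        assert 1 / (res.n_perm + 1) <= res.p <= 1.0

    def test_seed_determinism(self, rng):
        stats_map = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=40))}
        a = preranked_enrichment(stats_map, ["g1", "g5", "g9"], n_perm=150, seed=42)
        b = preranked_enrichment(stats_map, ["g1", "g5", "g9"], n_perm=150, seed=42)
        assert a == b

    def test_pvalue_calibration(self):
        # under random gene sets the p-values should be ~uniform
        rng = np.random.default_rng(123)
        stats_map = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=80))}
        pvals = []
        for rep in range(200):
            gene_set = rng.choice(80, size=8, replace=False)
            res = preranked_enrichment(
                stats_map, [f"g{i}" for i in gene_set], n_perm=200, seed=1000 + rep
            )
            pvals.append(res.p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# hypergeometric_enrichment


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_enrichment(0, 5, 4, 10) == 1.0

    def test_derived_value(self):
        # C(5,4) C(5,0) / C(10,4) = 5/210
        assert hypergeometric_enrichment(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_saturated_draw(self):
        assert hypergeometric_enrichment(6, 6, 6, 6) == pytest.approx(1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = sum(
                math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                for i in range(k, min(K, n) + 1)
                if n - i <= N - K
            )
            assert hypergeometric_enrichment(k, K, n, N) == pytest.approx(
                expected, abs=1e-10
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 4, 10)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 11, 4, 10)


# ---------------------------------------------------------------------------
# select_stem_threshold / classify_stem_like


class TestThreshold:
    def test_derived_four_candidates(self):
        scores = scores_from([0.90, 0.95, 0.50, 0.88])
        flags = [True, True, False, False]
        d = select_stem_threshold(scores, flags)
        assert d.threshold == pytest.approx(0.90)
        assert d.precision_at_threshold == 1.0
        assert d.group_sizes == (2, 2)
        assert d.candidates_examined == 4

    def test_perfect_separation(self):
        scores = scores_from([0.9, 0.85, 0.95, 0.2, 0.3])
        flags = [True, True, True, False, False]
        d = select_stem_threshold(scores, flags)
        assert d.threshold == pytest.approx(0.85)
        assert d.precision_at_threshold == 1.0

    def test_exhaustive_scan_oracle(self, rng):
        for _ in range(20):
            vals = np.round(rng.random(15), 2)
            flags = rng.random(15) < 0.4
            if flags.all() or not flags.any():
                continue
            d = select_stem_threshold(scores_from(vals.tolist()), flags.tolist())
            best = max(
                (flags[vals >= t].mean() for t in np.unique(vals)),
            )
            assert d.precision_at_threshold == pytest.approx(best)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            select_stem_threshold(scores_from([0.5, 0.6]), [True, True])

    def test_undefined_scores_rejected(self):
        with pytest.raises(ValueError, match="defined"):
            select_stem_threshold(scores_from([0.5, None, 0.9]), [False, False, True])

    def test_classify_matches_decision_group_sizes(self, rng):
        vals = np.round(rng.random(30), 2)
        flags = (rng.random(30) < 0.3)
        flags[0], flags[1] = True, False
        d = select_stem_threshold(scores_from(vals.tolist()), flags.tolist())
        labels = classify_stem_like(scores_from(vals.tolist()), d.threshold)
        assert labels.count("stem-like") == d.group_sizes[0]
        assert labels.count("other") == d.group_sizes[1]


class TestClassify:
    def test_paper_threshold_example(self):
        labels = classify_stem_like(scores_from([0.90, 0.50]), 0.862)
        assert labels == ["stem-like", "other"]

    def test_threshold_zero_all_stem(self):
        assert classify_stem_like(scores_from([0.1, 0.0]), 0.0) == ["stem-like"] * 2

    def test_threshold_one_none_stem(self):
        assert classify_stem_like(scores_from([0.99, 0.5]), 1.0) == ["other"] * 2

    def test_undefined_goes_other_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            labels = classify_stem_like(scores_from([0.9, None]), 0.5)
        assert labels == ["stem-like", "other"]


# ---------------------------------------------------------------------------
# select_root_state


class TestRootState:
    def test_argmax(self):
        scores = scores_from([0.9, 0.9, 0.3, 0.5, 0.5])
        call = select_root_state(scores, ["S1", "S1", "S2", "S3", "S3"])
        assert call.root_state == "S1"
        assert call.state_means == {"S1": 0.9, "S2": 0.3, "S3": 0.5}

    def test_tie_breaks_lexicographically(self):
        scores = scores_from([0.7, 0.7, 0.2, 0.2])
        with pytest.warns(UserWarning, match="tie"):
            call = select_root_state(scores, ["B", "A", "B", "A"])
        assert call.root_state == "A"

    def test_state_without_defined_scores_rejected(self):
        scores = scores_from([0.9, None])
        with pytest.raises(ValueError, match="S2"):
            select_root_state(scores, ["S1", "S2"])

    def test_needs_two_states(self):
        with pytest.raises(ValueError, match="two states"):
            select_root_state(scores_from([0.5, 0.6]), ["S1", "S1"])


# ---------------------------------------------------------------------------
# select_hvg


class TestSelectHvg:
    def _dataset(self, matrix):
        genes = [f"g{i}" for i in range(len(matrix))]
        samples = [f"s{j}" for j in range(len(matrix[0]))]
        return ExpressionDataset.from_arrays("d", np.asarray(matrix, float), genes, samples)

    def test_detection_floor_strict(self):
        # g0 detected in 9 cells, g1 in 10
        matrix = np.ones((2, 12)) + np.arange(12) * 0.01  # avoid zero variance
        matrix[0, :3] = 0.0
        matrix[1, :2] = 0.0
        ds = self._dataset(matrix)
        got = select_hvg(ds, min_cells=10, top_n=5)
        assert got == ["g1"]

    def test_variance_over_mean_ranking(self):
        ds = self._dataset([[1, 3], [2, 2]])
        assert select_hvg(ds, min_cells=1, top_n=2) == ["g0", "g1"]

    def test_matches_full_sort_oracle(self, rng):
        X = rng.lognormal(size=(40, 15))
        X[rng.random(X.shape) < 0.3] = 0.0
        ds = self._dataset(X)
        got = select_hvg(ds, min_cells=5, top_n=10)
        detected = (X > 0).sum(axis=1)
        stats_ = []
        for i in range(40):
            if detected[i] < 5 or X[i].mean() == 0:
                continue
            stats_.append((X[i].var(ddof=1) / X[i].mean(), f"g{i}"))
        expected = [g for _, g in sorted(stats_, key=lambda t: (-t[0], t[1]))[:10]]
        assert got == expected

    def test_gene_order_invariance(self, rng):
        X = rng.lognormal(size=(20, 10))
        ds = self._dataset(X)
        perm = rng.permutation(20)
        shuffled = ExpressionDataset(
            "p", ds.values.iloc[perm]
        )
        assert set(select_hvg(ds, 1, 8)) == set(select_hvg(shuffled, 1, 8))


# ---------------------------------------------------------------------------
# compare_groups


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0) or (t == pytest.approx(0.0) and p == pytest.approx(1.0))

    def test_hand_computed_pooled(self):
        t, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_swap_negates_t(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, size=9)
        t1, p1 = compare_groups(a, b)
        t2, p2 = compare_groups(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_equal_constant_groups(self):
        assert compare_groups([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_welch_option(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=12) * 3
        ref = stats.ttest_ind(a, b, equal_var=False)
        t, p = compare_groups(a, b, equal_variance=False)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="two values"):
            compare_groups([1.0], [2.0, 3.0])
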