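"""NB Wald test, effect sizes, Fisher enrichment, ranking metric and GSEA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cimpomics.features import GenomicInterval
from cimpomics.quantify import CountMatrix
from cimpomics.stats import (bh_adjust, fisher_region_enrichment, nb_wald,
                             preranked_gsea, rank_metric, welch_cohen)


def two_group_matrix(seed=0, n_feat=50, n1=4, n2=4, mu=100.0, disp=0.1,
                     lfc_features=None):
    rng = np.random.default_rng(seed)
    mean = np.full((n_feat, n1 + n2), mu)
    if lfc_features:
        for f, lfc in lfc_features.items():
            mean[f, n1:] *= 2.0 ** lfc
    shape = 1.0 / disp
    counts = rng.poisson(rng.gamma(shape, mean * disp))
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    groups = {c: ("g1" if c.startswith("a") else "g2") for c in cols}
    return CountMatrix(pd.DataFrame(counts, columns=cols), groups)


class TestNbWald:
    def test_all_zero_feature_flagged_na(self):
        cm = two_group_matrix(seed=1, n_feat=5)
        cm.matrix.iloc[0] = 0
        res = nb_wald(cm, ("g1", "g2"))
        assert res.iloc[0]["status"] == "all-zero"
        assert np.isnan(res.iloc[0]["pvalue"])
        assert len(res) == 5  # flagged, not dropped

    def test_contrast_swap_negates_lfc_preserves_p(self):
        cm = two_group_matrix(seed=2, n_feat=30, lfc_features={0: 2.0})
        fwd = nb_wald(cm, ("g1", "g2"))
        rev = nb_wald(cm, ("g2", "g1"))
        np.testing.assert_allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-8)
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-10)

    def test_strong_effect_detected(self):
        cm = two_group_matrix(seed=3, n_feat=40, n1=6, n2=6,
                              lfc_features={0: -3.0, 1: 3.0})
        res = nb_wald(cm, ("g1", "g2"))
        assert res.iloc[0]["FDR"] < 0.01 and res.iloc[0]["log2FC"] < -2
        assert res.iloc[1]["FDR"] < 0.01 and res.iloc[1]["log2FC"] > 2

    def test_small_group_errors(self):
        cm = two_group_matrix(n1=1, n2=4)
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_wald(cm, ("g1", "g2"))

    def test_unknown_group_errors(self):
        cm = two_group_matrix()
        with pytest.raises(ValueError, match="unknown group"):
            nb_wald(cm, ("g1", "nope"))

    def test_fdr_at_least_p(self):
        cm = two_group_matrix(seed=5, n_feat=100)
        res = nb_wald(cm, ("g1", "g2")).dropna(subset=["pvalue"])
        assert (res["FDR"] >= res["pvalue"] - 1e-12).all()
        assert res["FDR"].between(0, 1).all()


class TestNbWaldCrossValidation:
    def test_agrees_with_pydeseq2_fold_changes(self):
        """Independent NB GLM route: estimates track DESeq2's on shared data."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(0)
        n_feat, n1, n2 = 60, 6, 6
        mean = np.full((n_feat, n1 + n2), 150.0)
        mean[0, n1:] *= 8
        mean[1, n1:] /= 8
        counts = rng.poisson(rng.gamma(10.0, mean * 0.1))
        features = [f"f{i}" for i in range(n_feat)]
        cdf = pd.DataFrame(counts.T, columns=features)
        meta = pd.DataFrame({"condition": ["A"] * n1 + ["B"] * n2},
                            index=cdf.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=cdf, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            stat = DeseqStats(dds, contrast=["condition", "B", "A"],
                              quiet=True)
            stat.summary()
        ref = stat.results_df

        cm = CountMatrix(
            pd.DataFrame(counts, index=features, columns=cdf.index),
            {s: ("A" if i < n1 else "B") for i, s in enumerate(cdf.index)})
        ours = nb_wald(cm, ("A", "B"))
        diff = (ours["log2FC"] - ref["log2FoldChange"].to_numpy()).abs()
        assert diff.median() < 0.15
        # both routes call the two planted features and agree on direction
        assert ours.iloc[0]["FDR"] < 0.01 and ref.iloc[0]["padj"] < 0.01
        assert ours.iloc[1]["log2FC"] < 0 and ref.iloc[1]["log2FoldChange"] < 0


class TestWelchCohen:
    def test_identical_means_zero_d(self):
        r = welch_cohen([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert r.cohen_d == pytest.approx(0.0)

    def test_analytic_unit_d(self):
        # means 2 and 1, both sds exactly 1
        g1 = [1.0, 2.0, 3.0]  # mean 2, sd 1
        g2 = [0.0, 1.0, 2.0]  # mean 1, sd 1
        r = welch_cohen(g1, g2)
        assert r.cohen_d == pytest.approx(1.0)
        assert r.size_label == "large"

    def test_size_labels(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 2000)
        small = welch_cohen(base + 0.1, base)
        assert small.size_label == "small"
        large = welch_cohen(base + 0.9, base)
        assert large.size_label == "large"
        medium = welch_cohen(base + 0.5, base)
        assert medium.size_label == "medium"

    def test_constant_groups_flagged(self):
        r = welch_cohen([1.0, 1.0], [1.0, 1.0])
        assert r.flagged and math.isnan(r.cohen_d)

    @settings(deadline=None, max_examples=100)
    @given(
        vals=st.lists(st.floats(-50, 50), min_size=4, max_size=10),
        c=st.floats(0.1, 20),
    )
    def test_scale_equivariance(self, vals, c):
        g1 = vals[: len(vals) // 2]
        g2 = vals[len(vals) // 2:]
        if len(g1) < 2 or len(g2) < 2:
            return
        r1 = welch_cohen(g1, g2)
        r2 = welch_cohen([v * c for v in g1], [v * c for v in g2])
        if not (r1.flagged or r2.flagged):
            assert r2.cohen_d == pytest.approx(r1.cohen_d, rel=1e-6, abs=1e-9)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(9)
        g1, g2 = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        r = welch_cohen(g1, g2)
        t, p = sps.ttest_ind(g1, g2, equal_var=False)
        assert r.welch_t == pytest.approx(t)
        assert r.welch_p == pytest.approx(p)


class TestFisherEnrichment:
    def _intervals(self, positions, chrom="chr1", width=100, prefix="iv"):
        return [GenomicInterval(chrom, p, p + width, ".", f"{prefix}{i}")
                for i, p in enumerate(positions)]

    def test_known_table(self):
        # universe of 100 regions; query = first 10; set covers 8 of the
        # query and 10 of the rest -> table (8, 2, 10, 80), OR 32
        universe = self._intervals(range(0, 100_000, 1000))
        query = universe[:10]
        member_positions = [iv.start for iv in universe[:8]] + [
            iv.start for iv in universe[10:20]
        ]
        db = {"set": self._intervals(member_positions, prefix="db", width=50)}
        res = fisher_region_enrichment(query, universe, db)
        row = res.loc["set"]
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 10, 80)
        assert row["odds_ratio"] == pytest.approx(32.0)
        # exact hypergeometric tail oracle
        expected_p = sps.hypergeom.sf(7, 100, 18, 10)
        assert row["pvalue"] == pytest.approx(expected_p, rel=1e-9)

    def test_perfect_coincidence_flagged(self):
        universe = self._intervals(range(0, 40_000, 1000))
        query = universe[:20]
        db = {"set": query}
        res = fisher_region_enrichment(query, universe, db)
        assert res.loc["set", "flagged"]
        assert math.isinf(res.loc["set", "odds_ratio"])
        assert res.loc["set", "pvalue"] < 1e-9

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_region_enrichment([], [], {"s": []})

    def test_independent_query_null_p_uniform(self):
        rng = np.random.default_rng(6)
        universe = self._intervals(range(0, 500_000, 1000))
        db = {"set": [iv for iv in universe if rng.random() < 0.3]}
        pvals = []
        for _ in range(80):
            pick = rng.choice(len(universe), size=100, replace=False)
            query = [universe[i] for i in pick]
            res = fisher_region_enrichment(query, universe, db)
            pvals.append(res.loc["set", "pvalue"])
        # discrete p-values are stochastically >= uniform for one-sided Fisher
        assert sps.kstest(pvals, "uniform", alternative="greater").pvalue > 0.01


class TestRankMetric:
    def _diff(self, rows):
        return pd.DataFrame(rows, columns=["log2FC", "FDR"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_signed_metric(self):
        d = self._diff([(-1.0, 0.01), (2.0, 1.0), (1.0, 0.0)])
        m = rank_metric(d)
        assert m["g0"] == pytest.approx(-2.0)
        assert m["g1"] == pytest.approx(0.0)
        assert m["g2"] == pytest.approx(320.0)  # underflow capped

    def test_na_excluded_and_sorted(self):
        d = self._diff([(1.0, 0.5), (np.nan, 0.5), (-1.0, 0.001)])
        m = rank_metric(d)
        assert "g1" not in m.index
        assert list(m.index) == ["g0", "g2"]


def brute_force_es(metric, genes, members, weight=1.0):
    nr = sum(abs(m) ** weight for g, m in zip(genes, metric) if g in members)
    nh = sum(1 for g in genes if g in members)
    p_miss = 1.0 / (len(genes) - nh)
    run, best = 0.0, 0.0
    for g, m in zip(genes, metric):
        if g in members:
            run += (abs(m) ** weight / nr) if nr > 0 else 1.0 / nh
        else:
            run -= p_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def test_es_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            metric = np.sort(rng.normal(0, 2, 10))[::-1]
            genes = [f"g{i}" for i in range(10)]
            members = set(rng.choice(genes, size=3, replace=False))
            ranked = pd.Series(metric, index=genes)
            res = preranked_gsea(ranked, {"s": members}, min_size=3,
                                 n_perm=10, seed=0)
            assert res.loc["s", "ES"] == pytest.approx(
                brute_force_es(metric, genes, members), abs=1e-12)

    def test_top_set_extreme_es(self):
        genes = [f"g{i}" for i in range(1000)]
        ranked = pd.Series(np.arange(1000, 0, -1, dtype=float), index=genes)
        res = preranked_gsea(ranked, {"top": genes[:20]}, n_perm=50, seed=0)
        assert res.loc["top", "ES"] >= 0.9

    def test_complement_identity_weight_zero(self):
        # classic KS identity: ES of the complement is the negative
        genes = [f"g{i}" for i in range(12)]
        ranked = pd.Series(np.linspace(3, -3, 12), index=genes)
        members = {"g0", "g3", "g7", "g8"}
        complement = set(genes) - members
        r1 = preranked_gsea(ranked, {"s": members}, min_size=1, n_perm=5,
                            weight=0.0, seed=0)
        r2 = preranked_gsea(ranked, {"c": complement}, min_size=1, n_perm=5,
                            weight=0.0, seed=0)
        assert r1.loc["s", "ES"] == pytest.approx(-r2.loc["c", "ES"], abs=1e-12)

    def test_small_sets_skipped(self):
        genes = [f"g{i}" for i in range(100)]
        ranked = pd.Series(np.linspace(3, -3, 100), index=genes)
        res = preranked_gsea(ranked, {"tiny": genes[:5]}, min_size=15,
                             n_perm=10, seed=0)
        assert len(res) == 0

    def test_determinism(self):
        genes = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(3)
        ranked = pd.Series(np.sort(rng.normal(size=200))[::-1], index=genes)
        sets = {"s": list(rng.choice(genes, 25, replace=False))}
        r1 = preranked_gsea(ranked, sets, n_perm=100, seed=42)
        r2 = preranked_gsea(ranked, sets, n_perm=100, seed=42)
        pd.testing.assert_frame_equal(r1, r2)


class TestBH:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert adj.max() <= 1.0
        assert (adj >= p - 1e-12).all()

    def test_nan_passthrough(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and not np.isnan(adj[0])
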