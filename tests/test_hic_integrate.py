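"""TAD boundary annotation, EP-loop calling, 3D differential and CTCF linkage."""

import numpy as np
import pandas as pd
import pytest

from cimpomics.features import GenomicInterval
from cimpomics.hic_integrate import (annotate_boundaries, call_ep_loops,
                                     ctcf_loop_linkage, differential_3d,
                                     loop_expression_correlation, pad_anchor,
                                     summarize_ctcf_3d_overlap, tad_boundaries)


def iv(chrom, s, e, id_=None):
    return GenomicInterval(chrom, s, e, ".", id_)


class TestBoundaries:
    def test_width_and_centering(self):
        left, right = tad_boundaries(iv("chr1", 100_000, 400_000))
        assert (left.start, left.end) == (97_500, 102_500)
        assert (right.start, right.end) == (397_500, 402_500)

    def test_smallest_fdr_peak_kept(self):
        tads = [iv("chr1", 100_000, 400_000, "t1")]
        peaks = [iv("chr1", 98_000, 99_000, "pA"), iv("chr1", 99_500, 100_500, "pB")]
        d = pd.DataFrame({"log2FC": [1.0, -1.0], "FDR": [0.3, 0.01]},
                         index=["pA", "pB"])
        res = annotate_boundaries(tads, d, peaks)
        left = res[(res["tad_id"] == "t1") & (res["side"] == "left")].iloc[0]
        assert left["ctcf_peak"] == "pB"

    def test_no_peak_still_emitted(self):
        tads = [iv("chr1", 100_000, 400_000, "t1")]
        res = annotate_boundaries(tads, pd.DataFrame(columns=["log2FC", "FDR"]), [])
        assert len(res) == 2
        assert res["ctcf_peak"].isna().all() or (res["ctcf_peak"] == None).all()  # noqa: E711

    def test_fdr_tie_breaks_by_start(self):
        tads = [iv("chr1", 100_000, 400_000, "t1")]
        peaks = [iv("chr1", 99_500, 100_200, "pA"), iv("chr1", 98_000, 99_000, "pB")]
        d = pd.DataFrame({"log2FC": [1.0, -1.0], "FDR": [0.01, 0.01]},
                         index=["pA", "pB"])
        res = annotate_boundaries(tads, d, peaks)
        left = res[res["side"] == "left"].iloc[0]
        assert left["ctcf_peak"] == "pB"  # smaller genomic start

    def test_order_invariance(self):
        tads = [iv("chr1", 100_000, 400_000, "t1")]
        peaks = [iv("chr1", 98_000, 99_000, "pA"), iv("chr1", 99_500, 100_500, "pB")]
        d = pd.DataFrame({"log2FC": [1.0, -1.0], "FDR": [0.3, 0.01]},
                         index=["pA", "pB"])
        r1 = annotate_boundaries(tads, d, peaks)
        r2 = annotate_boundaries(tads, d.iloc[::-1], peaks[::-1])
        pd.testing.assert_frame_equal(r1, r2)


def loop_row(s1, e1, s2, e2, name="L1"):
    return {"chrom1": "chr1", "start1": s1, "end1": e1,
            "chrom2": "chr1", "start2": s2, "end2": e2,
            "name": name, "score": 0.0}


class TestEpLoops:
    def test_ep_on_opposite_anchors(self):
        loops = pd.DataFrame([loop_row(100_000, 105_000, 500_000, 505_000)])
        # padded anchor1 [95k,110k); enhancer 10 kb away
        enhancers = [iv("chr1", 120_000, 121_000, "e1")]
        promoters = [iv("chr1", 510_000, 512_000, "gA")]  # 0 gap to padded a2
        res = call_ep_loops(loops, enhancers, promoters)
        assert res.iloc[0]["is_ep"]
        assert res.iloc[0]["gene_id"] == "gA"

    def test_same_anchor_only_not_ep(self):
        loops = pd.DataFrame([loop_row(100_000, 105_000, 500_000, 505_000)])
        enhancers = [iv("chr1", 111_000, 112_000, "e1")]
        promoters = [iv("chr1", 113_000, 114_000, "gA")]
        res = call_ep_loops(loops, enhancers, promoters)
        assert not res.iloc[0]["is_ep"]

    def test_inclusive_25kb(self):
        loops = pd.DataFrame([loop_row(100_000, 105_000, 500_000, 505_000)])
        # padded anchor1 ends at 110000; gap to enhancer start 135000 == 25000
        enhancers = [iv("chr1", 135_000, 136_000, "e1")]
        promoters = [iv("chr1", 500_000, 505_000, "gA")]
        res = call_ep_loops(loops, enhancers, promoters)
        assert res.iloc[0]["is_ep"]
        # one bp farther -> excluded
        enhancers = [iv("chr1", 135_001, 136_001, "e1")]
        res = call_ep_loops(loops, enhancers, promoters)
        assert not res.iloc[0]["is_ep"]

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(8)
        loops = pd.DataFrame([
            loop_row(int(a), int(a) + 5000, int(b), int(b) + 5000, f"L{i}")
            for i, (a, b) in enumerate(
                zip(rng.integers(0, 900_000, 40),
                    rng.integers(1_000_000, 1_900_000, 40)))
        ])
        enhancers = [iv("chr1", int(p), int(p) + 800, f"e{i}")
                     for i, p in enumerate(rng.integers(0, 2_000_000, 30))]
        promoters = [iv("chr1", int(p), int(p) + 2000, f"g{i}")
                     for i, p in enumerate(rng.integers(0, 2_000_000, 30))]
        res = call_ep_loops(loops, enhancers, promoters)

        def gap(a, b):
            if a.chrom != b.chrom:
                return 10 ** 12
            if a.start < b.end and b.start < a.end:
                return 0
            return b.start - a.end if b.start >= a.end else a.start - b.end

        for i, r in res.iterrows():
            a1 = pad_anchor("chr1", loops.iloc[i]["start1"], loops.iloc[i]["end1"])
            a2 = pad_anchor("chr1", loops.iloc[i]["start2"], loops.iloc[i]["end2"])
            brute = any(
                gap(ea, e) <= 25_000 and gap(pa, p) <= 25_000
                for ea, pa in ((a1, a2), (a2, a1))
                for e in enhancers for p in promoters
            )
            assert bool(r["is_ep"]) == brute


class TestDifferential3d:
    def _scores(self, seed=0, n=60, n1=5, n2=5, planted=None):
        rng = np.random.default_rng(seed)
        mean = np.full((n, n1 + n2), 200.0)
        if planted:
            for f, fold in planted.items():
                mean[f, n1:] *= fold
        counts = rng.poisson(rng.gamma(10.0, mean / 10.0))
        cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        groups = {c: ("g1" if c.startswith("a") else "g2") for c in cols}
        return pd.DataFrame(counts, columns=cols), groups

    def test_identical_groups_no_hits(self):
        scores, groups = self._scores(seed=1)
        res = differential_3d(scores, groups, ("g1", "g2"))
        assert res.attrs["mode"] == "nb-wald"
        assert (res["FDR"].dropna() > 0.05).all()

    def test_planted_fold_change_recovered(self):
        scores, groups = self._scores(seed=2, planted={0: 0.25, 1: 4.0})
        res = differential_3d(scores, groups, ("g1", "g2"))
        assert res.iloc[0]["FDR"] < 0.05 and res.iloc[0]["log2FC"] < -1
        assert res.iloc[1]["FDR"] < 0.05 and res.iloc[1]["log2FC"] > 1

    def test_swapped_contrast_negates(self):
        scores, groups = self._scores(seed=3, planted={0: 0.25})
        fwd = differential_3d(scores, groups, ("g1", "g2"))
        rev = differential_3d(scores, groups, ("g2", "g1"))
        np.testing.assert_allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-8)

    def test_non_integer_scores_use_welch_mode(self):
        scores, groups = self._scores(seed=4)
        res = differential_3d(scores + 0.5, groups, ("g1", "g2"))
        assert res.attrs["mode"] == "welch-log"


class TestLinkage:
    def test_full_coupling_gives_fraction_one(self):
        # every lost loop anchored at a decreasing CTCF peak
        loops = pd.DataFrame([loop_row(100_000, 105_000, 500_000, 505_000, "L0"),
                              loop_row(700_000, 705_000, 900_000, 905_000, "L1")])
        diff_loops = pd.DataFrame({"log2FC": [-2.0, 2.0], "FDR": [0.001, 0.001]},
                                  index=["L0", "L1"])
        peaks = [iv("chr1", 101_000, 102_000, "c0"),
                 iv("chr1", 701_000, 702_000, "c1")]
        diff_ctcf = pd.DataFrame({"log2FC": [-3.0, 2.0], "FDR": [0.001, 0.001]},
                                 index=["c0", "c1"])
        res = ctcf_loop_linkage(diff_loops, loops, diff_ctcf, peaks)
        assert res["lost_frac_ctcf_decrease"] == 1.0
        assert res["gained_frac_ctcf_decrease"] == 0.0
        assert res["n_lost"] == 1 and res["n_gained"] == 1

    def test_fractions_bounded(self, small_cohort):
        c = small_cohort
        from cimpomics.quantify import tmm_factors
        from cimpomics.stats import nb_wald
        diff_loops = differential_3d(c.loop_scores, c.groups, ("AML", "CIMP"))
        diff_ctcf = nb_wald(c.assays["ctcf"], ("AML", "CIMP"),
                            tmm_factors(c.assays["ctcf"])).rename(
            index=lambda r: r.replace("ctcfpk_", ""))
        loops = pd.DataFrame([
            {"chrom1": l["anchor1"].chrom, "start1": l["anchor1"].start,
             "end1": l["anchor1"].end, "chrom2": l["anchor2"].chrom,
             "start2": l["anchor2"].start, "end2": l["anchor2"].end,
             "name": l["id"], "score": 0.0}
            for l in c.genome.loop_truth])
        ctcf_ivs = [iv(s.interval.chrom, max(0, s.interval.start - 400),
                       s.interval.end + 400, s.id) for s in c.genome.ctcf_sites]
        res = ctcf_loop_linkage(diff_loops, loops, diff_ctcf, ctcf_ivs)
        for key in ("lost_frac_ctcf_decrease", "gained_frac_ctcf_decrease"):
            assert 0.0 <= res[key] <= 1.0


class TestLoopExpression:
    def test_identical_fold_changes(self):
        d = pd.DataFrame({"log2FC": [1.0, -2.0, 0.5], "FDR": [0.01] * 3,
                          "gene_id": ["g0", "g1", "g2"]},
                         index=["L0", "L1", "L2"])
        expr = pd.DataFrame({"log2FC": [1.0, -2.0, 0.5], "FDR": [0.01] * 3},
                            index=["g0", "g1", "g2"])
        res = loop_expression_correlation(d, expr)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_shuffled_assignment_decorrelates(self):
        rng = np.random.default_rng(5)
        lfc = rng.normal(0, 2, 200)
        genes = [f"g{i}" for i in range(200)]
        d = pd.DataFrame({"log2FC": lfc, "FDR": 0.01,
                          "gene_id": list(rng.permutation(genes))},
                         index=[f"L{i}" for i in range(200)])
        expr = pd.DataFrame({"log2FC": lfc, "FDR": 0.01}, index=genes)
        res = loop_expression_correlation(d, expr)
        assert abs(res["spearman_rho"]) < 0.15


class TestOverlapSummary:
    def test_peaks_inside_boundaries(self):
        peaks = [iv("chr1", 100, 200, "p0"), iv("chr1", 5000, 5100, "p1")]
        boundaries = [iv("chr1", 0, 10_000)]
        res = summarize_ctcf_3d_overlap(peaks, boundaries, [])
        assert res["frac_boundary"] == 1.0
        assert res["frac_anchor"] == 0.0

    def test_uniform_peaks_match_expected_fraction(self):
        rng = np.random.default_rng(6)
        genome = 10_000_000
        boundaries = [iv("chr1", s, s + 5000)
                      for s in range(0, genome, 250_000)]
        cover = sum(b.width for b in boundaries) / genome
        peaks = [iv("chr1", int(p), int(p) + 200, f"p{i}")
                 for i, p in enumerate(rng.integers(0, genome - 200, 4000))]
        res = summarize_ctcf_3d_overlap(peaks, boundaries, [])
        assert res["frac_boundary"] == pytest.approx(cover, abs=0.02)

    def test_stratified_fractions_recombine(self):
        rng = np.random.default_rng(7)
        peaks = [iv("chr1", int(p), int(p) + 200, f"p{i}")
                 for i, p in enumerate(rng.integers(0, 1_000_000, 500))]
        boundaries = [iv("chr1", s, s + 5000) for s in range(0, 1_000_000, 50_000)]
        variable = {f"p{i}" for i in range(0, 500, 3)}
        res = summarize_ctcf_3d_overlap(peaks, boundaries, [], variable)
        weighted = (res["frac_boundary_variable"] * res["n_variable"]
                    + res["frac_boundary_unchanged"] * res["n_unchanged"]
                    ) / res["n_peaks"]
        assert weighted == pytest.approx(res["frac_boundary"])
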