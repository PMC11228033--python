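"""Synthetic cohort generator: determinism, planted structure, fixtures."""

import numpy as np
import pandas as pd
import pytest
from conftest import small_config

from cimpomics import io as cio
from cimpomics.synthetic_cohort import (CohortConfig, generate_genome,
                                        simulate_cohort, simulate_counts,
                                        simulate_variant_tables,
                                        write_fixture_bundle)


class TestGenerateGenome:
    def test_deterministic_serialization(self):
        cfg = small_config(seed=1)
        g1 = generate_genome(cfg)
        g2 = generate_genome(cfg)
        assert g1.serialize() == g2.serialize()

    def test_seed_sensitivity(self):
        g1 = generate_genome(small_config(seed=1))
        g2 = generate_genome(small_config(seed=2))
        assert {iv.id for iv in g1.cgi_truth} != {iv.id for iv in g2.cgi_truth}

    def test_zero_genes_errors(self):
        with pytest.raises(ValueError, match="n_genes"):
            generate_genome(small_config(n_genes=0))

    def test_genome_too_small_errors(self):
        with pytest.raises(ValueError, match="genome_length"):
            generate_genome(CohortConfig(n_genes=1000, genome_length=100_000))

    def test_tads_tile_without_overlap(self):
        g = generate_genome(small_config())
        by_chrom = {}
        for tad in g.tad_truth:
            by_chrom.setdefault(tad.chrom, []).append(tad)
        for tads in by_chrom.values():
            tads.sort(key=lambda t: t.start)
            for a, b in zip(tads, tads[1:]):
                assert a.end <= b.start

    def test_intervals_within_bounds(self):
        g = generate_genome(small_config())
        clens = g.chrom_lengths()
        for iv in g.cgi_truth + [s.interval for s in g.ctcf_sites]:
            assert 0 <= iv.start < iv.end <= clens[iv.chrom]

    def test_ep_loop_promoter_anchor_near_tss(self):
        g = generate_genome(small_config())
        tss = {gene.id: gene.tss for gene in g.genes}
        for loop in g.loop_truth:
            if loop["type"] != "EP":
                continue
            t = tss[loop["gene_id"]]
            d = min(
                abs(t - (a.start + a.end) // 2)
                for a in (loop["anchor1"], loop["anchor2"])
            )
            assert d <= 25_000


class TestSimulateCounts:
    def test_dispersion_validation(self):
        with pytest.raises(ValueError, match="dispersion"):
            simulate_cohort(small_config(nb_dispersion=-1.0))

    def test_deterministic(self):
        c1 = simulate_cohort(small_config(seed=9))
        c2 = simulate_cohort(small_config(seed=9))
        pd.testing.assert_frame_equal(c1.expression.matrix, c2.expression.matrix)
        pd.testing.assert_frame_equal(c1.assays["ctcf"].matrix,
                                      c2.assays["ctcf"].matrix)
        assert c1.ledger.silenced_tf_ids == c2.ledger.silenced_tf_ids

    def test_null_model_group_ratios_center_on_zero(self, null_cohort):
        m = null_cohort.expression.matrix
        groups = null_cohort.groups
        cimp = [s for s in m.columns if groups[s] == "CIMP"]
        aml = [s for s in m.columns if groups[s] == "AML"]
        # depth-normalize before comparing group means
        norm = m / m.sum(axis=0)
        ratios = np.log2(norm[cimp].mean(axis=1) + 1e-9) - np.log2(
            norm[aml].mean(axis=1) + 1e-9)
        assert abs(ratios.mean()) < 0.05

    def test_silenced_tf_expression_ratio(self):
        cfg = small_config(seed=21, n_genes=2000, genome_length=16_000_000,
                           effect_log2fc=-3.0, frac_silenced_tfs=0.5,
                           meth_expr_rho=0.0, ctcf_coupling_beta=0.0,
                           n_regions={"meth": 2100, "atac": 2300,
                                      "h3k27ac": 300, "ctcf": 100},
                           n_per_group={"CIMP": 10, "AML": 10, "T-ALL": 2,
                                        "HSPC": 2})
        c = simulate_cohort(cfg)
        sil = c.ledger.silenced_tf_ids
        assert len(sil) > 50
        m = c.expression.matrix
        norm = m / m.sum(axis=0)
        cimp = [s for s in m.columns if c.groups[s] == "CIMP"]
        aml = [s for s in m.columns if c.groups[s] == "AML"]
        ratio = np.log2(norm.loc[sil, cimp].mean(axis=1)
                        / norm.loc[sil, aml].mean(axis=1))
        assert np.median(ratio) == pytest.approx(-3.0, abs=0.4)

    def test_ctcf_coupling_reduces_counts_at_flagged_hyper_sites(self):
        cfg = small_config(seed=22, ctcf_coupling_beta=6.0,
                           n_regions={"meth": 260, "atac": 300,
                                      "h3k27ac": 160, "ctcf": 500})
        c = simulate_cohort(cfg)
        lost = c.ledger.lost_ctcf_site_ids
        assert len(lost) > 50
        m = c.assays["ctcf"].matrix
        norm = m / m.sum(axis=0)
        cimp = [s for s in m.columns if c.groups[s] == "CIMP"]
        aml = [s for s in m.columns if c.groups[s] == "AML"]
        rows = [f"ctcfpk_{sid}" for sid in lost]
        ratio = norm.loc[rows, cimp].mean(axis=1) / norm.loc[rows, aml].mean(axis=1)
        assert (ratio < 1).mean() >= 0.9

    def test_generator_mean_self_consistency(self):
        # NB(mean, disp): empirical mean within 3 SE at n = 10,000 draws
        from cimpomics.synthetic_cohort import _nb_draw
        rng = np.random.default_rng(0)
        mean, disp, n = 80.0, 0.15, 10_000
        draws = _nb_draw(rng, np.full(n, mean), disp)
        var = mean + disp * mean ** 2
        se = np.sqrt(var / n)
        assert abs(draws.mean() - mean) < 3 * se
        # variance within 3 SE of its sampling distribution (normal approx)
        se_var = var * np.sqrt(2.0 / (n - 1)) * np.sqrt(1 + disp * 2)
        assert abs(draws.var(ddof=1) - var) < 4 * se_var

    def test_library_sizes_span_threefold(self, small_cohort):
        m = small_cohort.expression.matrix.sum(axis=0)
        # planted scales span exactly 3x; NB noise keeps the ratio near 3
        assert m.max() / m.min() > 2.0


class TestVariantTables:
    def test_every_rule_branch_planted(self, small_cohort):
        truth = small_cohort.ledger.variant_truth
        reasons = set(truth["expected_fail_rule"]) - {""}
        expected = {
            "qc:strand_bias", "qc:depth_total", "qc:depth_alt",
            "qc:mapping_quality", "qc:base_quality",
            "qc:other_allele_fraction", "qc:alt_alignment_fraction",
            "qc:indel_length", "qc:simple_repeat", "qc:selfchain",
            "qc:metric-missing", "qc:snv_cluster",
            "somatic:region", "somatic:exonic_func", "somatic:vaf",
            "somatic:popfreq", "somatic:donor", "somatic:blacklist",
        }
        assert reasons == expected
        assert len(truth) >= 200

    def test_deterministic_tables(self):
        cfg = small_config(seed=30)
        g = generate_genome(cfg)
        t1, f1, truth1, _ = simulate_variant_tables(g, cfg)
        t2, f2, truth2, _ = simulate_variant_tables(g, cfg)
        pd.testing.assert_frame_equal(truth1, truth2)
        for caller in t1:
            pd.testing.assert_frame_equal(t1[caller], t2[caller])
        pd.testing.assert_frame_equal(f1, f2)

    def test_ledger_verdicts_match_brute_force_rules(self, small_cohort):
        """Independent re-evaluation of the written rules on the truth table."""
        truth = small_cohort.ledger.variant_truth

        def qc_pass(r):
            if pd.isna(r["depth_total"]):
                return False
            if r["in_capture_pad200"] and not (0 < r["strand_bias"] < 1):
                return False
            if r["depth_total"] < 8 or r["depth_alt"] < 4:
                return False
            if r["mapping_quality"] < 40 or r["base_quality"] < 30:
                return False
            if r["other_allele_fraction"] >= 0.4:
                return False
            if r["alt_alignment_fraction"] > 0.1:
                return False
            if r["indel_length"] >= 500:
                return False
            if r["in_simple_repeat"] or r["in_selfchain95"]:
                return False
            return True

        # per-site rules first
        site_pass = truth.apply(qc_pass, axis=1)
        # cluster rule on passing SNVs
        passing = truth[site_pass & (truth["type"] == "SNV")].sort_values(
            ["chrom", "pos"])
        clustered = set()
        run, prev = [], (None, None)
        for idx, r in passing.iterrows():
            if r["chrom"] == prev[0] and r["pos"] - prev[1] < 5:
                run.append(idx)
            else:
                if len(run) >= 3:
                    clustered.update(run)
                run = [idx]
            prev = (r["chrom"], r["pos"])
        if len(run) >= 3:
            clustered.update(run)
        final_qc = site_pass & ~truth.index.isin(clustered)
        assert (final_qc == truth["expected_qc_pass"]).all()

        def somatic(r):
            if r["region_func"] not in ("exonic", "splicing_acceptor"):
                return False
            if r["type"] == "SNV" and r["exonic_func"] in ("synonymous SNV",
                                                           "unknown"):
                return False
            if pd.isna(r["vaf"]) or r["vaf"] < 0.01:
                return False
            if r["popfreq"] > 0.0002 and not (
                r["cosmic_heme_count"] >= 5 or r["gene"] in ("DNMT3A", "TET2",
                                                             "ASXL1")
            ):
                return False
            if r["in_donor_set"] or r["in_panel_blacklist"]:
                return False
            return True

        got_somatic = final_qc & truth.apply(somatic, axis=1)
        assert (got_somatic == truth["expected_somatic"]).all()


class TestFixtureBundle:
    def test_round_trip(self, small_cohort, tmp_path):
        entries = write_fixture_bundle(small_cohort, tmp_path)
        names = {e["file"] for e in entries}
        assert "cgi_truth.bed" in names and "motifs.jaspar" in names

        # BED round trip
        cgis = cio.read_bed(tmp_path / "cgi_truth.bed")
        assert [(iv.chrom, iv.start, iv.end, iv.id) for iv in cgis] == [
            (iv.chrom, iv.start, iv.end, iv.id)
            for iv in small_cohort.genome.cgi_truth
        ]
        # count matrix round trip
        expr = cio.read_matrix(tmp_path / "counts_expression.tsv")
        pd.testing.assert_frame_equal(expr, small_cohort.expression.matrix,
                                      check_names=False)
        # FASTA round trip
        seqs = cio.read_fasta(tmp_path / "ctcf_motifs.fasta")
        assert seqs == {s.id: s.motif_seq for s in small_cohort.genome.ctcf_sites}
        # PWM round trip: counts preserved
        pwms = cio.read_jaspar_pfms(tmp_path / "motifs.jaspar")
        assert [m.matrix_id for m in pwms] == [
            m.matrix_id for m in small_cohort.pwms]

    def test_narrowpeak_has_ten_columns(self, small_cohort, tmp_path):
        write_fixture_bundle(small_cohort, tmp_path)
        sample = small_cohort.peaksets["atac"][0].sample_id
        path = tmp_path / f"peaks_atac_{sample}.narrowPeak"
        with open(path) as fh:
            for line in fh:
                assert len(line.rstrip("\n").split("\t")) == 10

    def test_bedpe_anchor_convention(self, small_cohort, tmp_path):
        write_fixture_bundle(small_cohort, tmp_path)
        loops = cio.read_bedpe(tmp_path / "loops.bedpe")
        same = loops[loops["chrom1"] == loops["chrom2"]]
        assert (same["start1"] < same["start2"]).all()
        assert (loops["start1"] < loops["end1"]).all()

    def test_checksums_reproducible(self, tmp_path):
        c1 = simulate_cohort(small_config(seed=17))
        c2 = simulate_cohort(small_config(seed=17))
        e1 = write_fixture_bundle(c1, tmp_path / "a")
        e2 = write_fixture_bundle(c2, tmp_path / "b")
        assert {x["file"]: x["sha256"] for x in e1} == {
            x["file"]: x["sha256"] for x in e2}
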