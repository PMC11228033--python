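"""End-to-end orchestration: simulate -> features -> quantify -> differential
-> integrations -> report.

``run_all`` executes the stages in dependency order on a synthetic cohort,
writes per-stage outputs, and returns a machine-readable report that is
byte-identically reproducible for a fixed config and seed (timestamps are
excluded by construction; floats are rounded before serialization).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import ctcf_coupling as ctcf_mod
from . import hic_integrate as hic
from . import integrate_expression as integ
from . import motif_activity as motif
from . import variant_sieve as sieve
from .features import GenomicInterval, classify_atac_peaks
from .quantify import CountMatrix, build_master_list, tmm_factors
from .stats import nb_wald
from .synthetic_cohort import (CohortConfig, SyntheticCohort, simulate_cohort,
                               write_fixture_bundle)

logger = logging.getLogger(__name__)

CONFIG_KEYS = {
    "seed", "n_per_group", "n_genes", "n_regions", "genome_length",
    "nb_dispersion", "effect_log2fc", "frac_silenced_tfs",
    "ctcf_coupling_beta", "loop_ctcf_coupling", "meth_expr_rho",
    "stages", "contrast",
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    bad = set(cfg) - CONFIG_KEYS
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return cfg


def _round_floats(obj, ndigits: int = 9):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def top_variance_select(matrix: pd.DataFrame, k: int = 5000,
                        transform=np.log1p) -> pd.DataFrame:
    """Top-k features by variance of transformed values (deterministic ties).

    Mirrors variance-stabilized top-variance selection with a log1p
    transform; ties break by feature id, and k larger than the feature
    count returns everything with a log notice.
    """
    t = transform(matrix.to_numpy(dtype=float))
    var = pd.Series(t.var(axis=1), index=matrix.index)
    if k >= len(var):
        if k > len(var):
            logger.warning("top_variance_select: k=%d > %d features", k, len(var))
        return matrix
    order = sorted(var.index, key=lambda f: (-var[f], str(f)))
    return matrix.loc[order[:k]]


def run_all(config: Mapping | CohortConfig | None = None,
            out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-cohort analysis; returns the run report."""
    stages = {"hic": True, "variants": True, "motifs": True}
    contrast = ("AML", "CIMP")
    if isinstance(config, CohortConfig):
        cc = config
    else:
        cfg = dict(config or {})
        stages.update(cfg.pop("stages", {}))
        contrast = tuple(cfg.pop("contrast", contrast))
        cc = CohortConfig(**cfg)
    report: dict = {"config": {"seed": cc.seed, "n_genes": cc.n_genes,
                               "contrast": list(contrast)},
                    "stages": {}}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- simulate ------------------------------------------------------------
    cohort = simulate_cohort(cc)
    if out_dir is not None:
        manifest = write_fixture_bundle(cohort, out_dir / "fixtures")
        report["input_checksums"] = {e["file"]: e["sha256"] for e in manifest}
    report["stages"]["simulate"] = {
        "n_samples": len(cohort.groups),
        "n_silenced_tfs": len(cohort.ledger.silenced_tf_ids),
        "n_lost_ctcf_sites": len(cohort.ledger.lost_ctcf_site_ids),
        "n_lost_loops": len(cohort.ledger.lost_loop_ids),
    }

    # -- features ------------------------------------------------------------
    atac_regions = cohort.region_index["atac"]
    labels = classify_atac_peaks(atac_regions, cohort.genome.tss_list())
    report["stages"]["features"] = {
        "n_atac_promoter_peaks": labels.count("promoter"),
        "n_atac_enhancer_peaks": labels.count("enhancer"),
        "n_cgi_truth": len(cohort.genome.cgi_truth),
    }

    # -- quantify ------------------------------------------------------------
    master = build_master_list(cohort.peaksets["atac"])
    diffs: dict[str, pd.DataFrame] = {}
    for assay, cm in cohort.assays.items():
        factors = tmm_factors(cm)
        diffs[assay] = nb_wald(cm, contrast, factors)
    expr_factors = tmm_factors(cohort.expression)
    diff_expr = nb_wald(cohort.expression, contrast, expr_factors)
    report["stages"]["quantify"] = {
        "n_master_peaks": len(master),
        "significant_per_assay": {
            a: int((d["FDR"] < 0.05).sum()) for a, d in diffs.items()
        },
        "n_significant_genes": int((diff_expr["FDR"] < 0.05).sum()),
    }

    # -- starburst integration ------------------------------------------------
    diff_meth_prom = diffs["meth"].loc[
        [i for i in diffs["meth"].index if i.startswith("meth_prom_")]
    ].rename(index=lambda rid: rid.replace("meth_prom_", ""))
    annot = pd.DataFrame(
        {"is_tf": {g.id: g.is_tf for g in cohort.genome.genes},
         "is_hematopoietic": {g.id: g.is_hematopoietic for g in cohort.genome.genes}}
    )
    records, star_summary = integ.starburst_join(
        diff_meth_prom, diff_expr, gene_annotation=annot
    )
    report["stages"]["starburst"] = star_summary
    if out_dir is not None:
        records.to_csv(out_dir / "starburst.tsv", sep="\t")

    # -- enhancer integration -------------------------------------------------
    enh_ivs = [iv for iv, _ in cohort.genome.enhancer_truth]
    loops_df = _loops_frame(cohort)
    # enhancer intervals are id'd enh_<gene>; their count rows atac_enh_<gene>
    enh_counts = cohort.assays["atac"].matrix.rename(
        index=lambda rid: "enh_" + rid[len("atac_enh_"):]
        if rid.startswith("atac_enh_") else rid
    )
    prom_counts = cohort.assays["atac"].matrix.rename(
        index=lambda rid: rid[len("atac_prom_"):]
        if rid.startswith("atac_prom_") else rid
    )
    emap = integ.assign_enhancers(
        enh_ivs, cohort.genome.tss_list(), cohort.genome.tad_truth, loops_df,
        enhancer_counts=enh_counts, promoter_counts=prom_counts,
        db_map={iv.id: gid for iv, gid in cohort.genome.enhancer_truth},
    )
    diff_atac_enh = diffs["atac"].loc[
        [i for i in diffs["atac"].index if i.startswith("atac_enh_")]
    ].rename(index=lambda rid: "enh_" + rid[len("atac_enh_"):])
    _, enh_summary = integ.enhancer_expression_join(diff_atac_enh, emap, diff_expr)
    truth = cohort.ledger.enhancer_targets
    n_correct = sum(
        1 for enh_id, row in emap.iterrows() if truth.get(enh_id) == row["gene_id"]
    )
    enh_summary["assignment_accuracy"] = n_correct / len(emap) if len(emap) else np.nan
    report["stages"]["enhancers"] = enh_summary

    # -- motif activity -------------------------------------------------------
    if stages.get("motifs", True):
        seqs = {pid: s for pid, s in cohort.peak_sequences.items()}
        matches = motif.scan_motifs(cohort.pwms, seqs)
        gc = pd.Series({pid: (s.count("G") + s.count("C")) / len(s)
                        for pid, s in seqs.items()})
        atac_cm = cohort.assays["atac"]
        scanned = CountMatrix(atac_cm.matrix.loc[list(seqs)], atac_cm.groups)
        dev = motif.deviations(scanned, matches, gc, seed=cc.seed)
        dma = motif.differential_motif_activity(
            dev, cohort.groups, contrast[1], contrast[0]
        )
        report["stages"]["motifs"] = {
            "n_motifs": int(len(dev)),
            "n_significant": int(dma["significant"].sum()),
            "planted_motif_significant": bool(
                cohort.ledger.planted_motif_id
                and dma.loc[cohort.ledger.planted_motif_id, "significant"]
            ),
        }

    # -- CTCF coupling --------------------------------------------------------
    site_seqs = {s.id: s.motif_seq for s in cohort.genome.ctcf_sites}
    diff_ctcf = diffs["ctcf"].rename(index=lambda rid: rid.replace("ctcfpk_", ""))
    classes = ctcf_mod.classify_ctcf_sites(diff_ctcf)
    ctcf_ivs = [
        GenomicInterval(s.interval.chrom, max(0, s.interval.start - 400),
                        s.interval.end + 400, ".", s.id)
        for s in cohort.genome.ctcf_sites
    ]
    meth_ivs = [iv for iv in cohort.region_index["meth"]
                if iv.id.startswith("meth_ctcf_")]
    coupling = ctcf_mod.coupling_correlation(
        diff_ctcf, diffs["meth"], ctcf_ivs, meth_ivs
    )
    lost_seqs = [site_seqs[i] for i in classes[classes == "lost"].index]
    other_seqs = [site_seqs[i] for i in classes[classes != "lost"].index]
    pos_enrich = None
    if lost_seqs and other_seqs:
        pos_enrich = ctcf_mod.positional_enrichment(lost_seqs, other_seqs)
    report["stages"]["ctcf"] = {
        "class_counts": classes.value_counts().to_dict(),
        "coupling_pearson_r": coupling["pearson_r"],
        "coupling_spearman_rho": coupling["spearman_rho"],
        "n_joined_regions": coupling["n"],
        "cpg5_significant": bool(pos_enrich is not None and pos_enrich.loc[5, "FDR"] < 0.05),
        "cpg15_significant": bool(pos_enrich is not None and pos_enrich.loc[15, "FDR"] < 0.05),
    }

    # -- Hi-C -----------------------------------------------------------------
    if stages.get("hic", True):
        diff_loops = hic.differential_3d(cohort.loop_scores, cohort.groups, contrast)
        diff_tads = hic.differential_3d(cohort.tad_scores, cohort.groups, contrast)
        prom_ivs = [
            GenomicInterval(g.chrom, max(0, g.tss - 1000), g.tss + 1000, g.strand, g.id)
            for g in cohort.genome.genes
        ]
        ep = hic.call_ep_loops(loops_df, enh_ivs, prom_ivs)
        linkage = hic.ctcf_loop_linkage(diff_loops, loops_df, diff_ctcf, ctcf_ivs)
        ep_diff = diff_loops.join(
            ep.set_index("name")[["is_ep", "gene_id"]], how="inner"
        )
        loop_expr = hic.loop_expression_correlation(
            ep_diff[ep_diff["is_ep"].fillna(False)], diff_expr
        )
        report["stages"]["hic"] = {
            "n_diff_loops": int((diff_loops["FDR"] < 0.05).sum()),
            "n_diff_tads": int((diff_tads["FDR"] < 0.05).sum()),
            "n_ep_loops": int(ep["is_ep"].sum()),
            "lost_frac_ctcf_decrease": linkage["lost_frac_ctcf_decrease"],
            "gained_frac_ctcf_decrease": linkage["gained_frac_ctcf_decrease"],
            "loop_expr_spearman_rho": loop_expr["spearman_rho"],
        }

    # -- variants -------------------------------------------------------------
    if stages.get("variants", True):
        res = sieve.run_sieve(cohort.variant_tables)
        artifact_db = {
            (r["gene5"], r["gene3"])
            for _, r in cohort.ledger.fusion_truth.iterrows() if r["in_artifact_db"]
        }
        fusions = sieve.fusion_majority_vote(
            cohort.fusion_tables, artifact_db=artifact_db
        )
        report["stages"]["variants"] = {
            "n_merged": int(len(res["merged"])),
            "n_qc_pass": int(len(res["qc_pass"])),
            "n_somatic": int(len(res["somatic"])),
            "n_oncogenic": int(res["somatic"]["oncogenic"].sum()),
            "n_fusions_kept": int(len(fusions)),
        }

    report = _round_floats(report)
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _loops_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    rows = []
    for loop in cohort.genome.loop_truth:
        a1, a2 = loop["anchor1"], loop["anchor2"]
        rows.append({
            "chrom1": a1.chrom, "start1": a1.start, "end1": a1.end,
            "chrom2": a2.chrom, "start2": a2.start, "end2": a2.end,
            "name": loop["id"], "score": 0.0,
        })
    return pd.DataFrame(rows)
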