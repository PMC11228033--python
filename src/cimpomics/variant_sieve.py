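"""Tumor-only somatic variant filtering cascade and fusion majority voting.

Variants from multiple callers are unified on normalized
(chrom, pos, ref, alt) keys, run through the quality cascade in a fixed
order (strand bias inside the padded capture, depth, alignment/base
quality, other-allele and alternative-alignment fractions, indel length,
repeat and self-chain regions, then post-hoc SNV cluster removal), and the
survivors through the somatic selection rules with the population-frequency
rescues (COSMIC hematological recurrence, clonal-hematopoiesis genes).
Every variant carries a complete ordered filter trail; a missing required
metric fails the variant with reason ``metric-missing``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CH_GENES = frozenset({"DNMT3A", "TET2", "ASXL1"})
ONCOGENIC_FUNCS = frozenset({
    "frameshift insertion", "frameshift deletion", "stopgain", "startloss",
})
SOMATIC_FUNC_FAIL = frozenset({"synonymous SNV", "unknown"})
REGION_PASS = frozenset({"exonic", "splicing_acceptor"})

QC_RULES = [
    ("strand_bias", ["strand_bias", "in_capture_pad200"]),
    ("depth_total", ["depth_total"]),
    ("depth_alt", ["depth_alt"]),
    ("mapping_quality", ["mapping_quality"]),
    ("base_quality", ["base_quality"]),
    ("other_allele_fraction", ["other_allele_fraction"]),
    ("alt_alignment_fraction", ["alt_alignment_fraction"]),
    ("indel_length", ["indel_length"]),
    ("simple_repeat", ["in_simple_repeat"]),
    ("selfchain", ["in_selfchain95"]),
]


# ---------------------------------------------------------------------------
# caller merging
# ---------------------------------------------------------------------------

def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Canonical (chrom, pos, ref, alt): shared prefix then suffix trimmed.

    Unifies redundant indel representations across callers (parsimony
    trimming; both alleles keep at least one base).
    """
    ref, alt = str(ref), str(alt)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return chrom, int(pos), ref, alt


def merge_caller_calls(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of per-caller variant tables keyed on normalized coordinates.

    Caller provenance is collected per variant; annotation/metric fields
    come from the first caller reporting the variant (they are shared
    annotations, not per-caller values).
    """
    records: dict[tuple, dict] = {}
    order: list[tuple] = []
    for caller in sorted(tables):
        df = tables[caller]
        for _, row in df.iterrows():
            key = normalize_variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            if key not in records:
                rec = row.to_dict()
                rec["chrom"], rec["pos"], rec["ref"], rec["alt"] = key
                rec["callers"] = {caller}
                records[key] = rec
                order.append(key)
            else:
                records[key]["callers"].add(caller)
    rows = []
    for key in sorted(order):
        rec = records[key]
        rec["callers"] = ",".join(sorted(rec["callers"]))
        rows.append(rec)
    return pd.DataFrame(rows) if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# quality cascade
# ---------------------------------------------------------------------------

def _qc_rule(name: str, row: pd.Series) -> bool | None:
    """True pass / False fail / None when a required metric is missing."""
    def val(col):
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    if name == "strand_bias":
        in_cap = val("in_capture_pad200")
        if in_cap is None:
            return None
        if not in_cap:
            return True
        sb = val("strand_bias")
        return None if sb is None else 0.0 < sb < 1.0
    if name == "depth_total":
        v = val("depth_total")
        return None if v is None else v >= 8
    if name == "depth_alt":
        v = val("depth_alt")
        return None if v is None else v >= 4
    if name == "mapping_quality":
        v = val("mapping_quality")
        return None if v is None else v >= 40
    if name == "base_quality":
        v = val("base_quality")
        return None if v is None else v >= 30
    if name == "other_allele_fraction":
        v = val("other_allele_fraction")
        return None if v is None else v < 0.40
    if name == "alt_alignment_fraction":
        v = val("alt_alignment_fraction")
        return None if v is None else v <= 0.10
    if name == "indel_length":
        v = val("indel_length")
        return None if v is None else v < 500
    if name == "simple_repeat":
        v = val("in_simple_repeat")
        return None if v is None else not v
    if name == "selfchain":
        v = val("in_selfchain95")
        return None if v is None else not v
    raise KeyError(name)


def _snv_clusters(passing: pd.DataFrame, max_gap: int = 5, min_run: int = 3) -> set:
    """Indices of passing SNVs in maximal runs of >= min_run with gaps < max_gap."""
    snvs = passing[passing["type"] == "SNV"].sort_values(["chrom", "pos"])
    clustered: set = set()
    run: list = []
    prev_chrom, prev_pos = None, None
    for idx, row in snvs.iterrows():
        if (
            row["chrom"] == prev_chrom
            and prev_pos is not None
            and row["pos"] - prev_pos < max_gap
        ):
            run.append(idx)
        else:
            if len(run) >= min_run:
                clustered.update(run)
            run = [idx]
        prev_chrom, prev_pos = row["chrom"], row["pos"]
    if len(run) >= min_run:
        clustered.update(run)
    return clustered


def apply_quality_filters(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the ordered per-site quality rules, then SNV cluster removal.

    Returns (pass, fail) DataFrames; both carry a serialized ``filter_trail``
    and the failing rows a ``fail_reason`` of the first failing rule
    (``qc:metric-missing`` when a required metric is absent).
    """
    df = variants.copy()
    trails: list[str] = []
    reasons: list[str] = []
    for _, row in df.iterrows():
        trail = []
        reason = ""
        for name, _cols in QC_RULES:
            verdict = _qc_rule(name, row)
            if verdict is None:
                trail.append(f"{name}:missing")
                if not reason:
                    reason = "qc:metric-missing"
            elif verdict:
                trail.append(f"{name}:pass")
            else:
                trail.append(f"{name}:fail")
                if not reason:
                    reason = f"qc:{name}"
        trails.append("|".join(trail))
        reasons.append(reason)
    df["filter_trail"] = trails
    df["fail_reason"] = reasons

    passing = df[df["fail_reason"] == ""].copy()
    clustered = _snv_clusters(passing)
    if clustered:
        df.loc[list(clustered), "fail_reason"] = "qc:snv_cluster"
        df.loc[list(clustered), "filter_trail"] += "|snv_cluster:fail"
        keep = [i for i in passing.index if i not in clustered]
        passing = df.loc[keep].copy()
    passing["filter_trail"] += "|snv_cluster:pass"
    df.loc[passing.index, "filter_trail"] = passing["filter_trail"]
    failed = df[df["fail_reason"] != ""].copy()
    return passing, failed


# ---------------------------------------------------------------------------
# somatic selection & oncogenic flags
# ---------------------------------------------------------------------------

SOMATIC_RULES = ("region", "exonic_func", "vaf", "popfreq", "donor", "blacklist")


def _somatic_rule(name: str, row: pd.Series) -> bool:
    if name == "region":
        return row.get("region_func") in REGION_PASS
    if name == "exonic_func":
        if row.get("type") in ("insertion", "deletion"):
            return True
        return row.get("exonic_func") not in SOMATIC_FUNC_FAIL
    if name == "vaf":
        v = row.get("vaf")
        return v is not None and not pd.isna(v) and v >= 0.01
    if name == "popfreq":
        pf = row.get("popfreq", 0.0) or 0.0
        if pf <= 0.0002:
            return True
        rescued = (row.get("cosmic_heme_count", 0) or 0) >= 5 or (
            row.get("gene") in CH_GENES
        )
        return bool(rescued)
    if name == "donor":
        return not bool(row.get("in_donor_set"))
    if name == "blacklist":
        return not bool(row.get("in_panel_blacklist"))
    raise KeyError(name)


def select_somatic(passing: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the somatic-candidate rules conjunctively with the stated rescues."""
    df = passing.copy()
    keep_mask = []
    for idx, row in df.iterrows():
        trail = df.at[idx, "filter_trail"] if "filter_trail" in df else ""
        ok = True
        for name in SOMATIC_RULES:
            verdict = _somatic_rule(name, row)
            trail += f"|{name}:{'pass' if verdict else 'fail'}"
            if not verdict and ok:
                df.at[idx, "fail_reason"] = f"somatic:{name}"
                ok = False
        df.at[idx, "filter_trail"] = trail
        keep_mask.append(ok)
    keep_mask = np.array(keep_mask, dtype=bool)
    return df[keep_mask].copy(), df[~keep_mask].copy()


def flag_oncogenic(candidates: pd.DataFrame) -> pd.DataFrame:
    """Probable-oncogenic flag: COSMIC, truncating consequence, or damaging majority."""
    df = candidates.copy()
    flags, sources = [], []
    for _, row in df.iterrows():
        src = []
        if bool(row.get("in_cosmic")):
            src.append("cosmic")
        if row.get("exonic_func") in ONCOGENIC_FUNCS:
            src.append("consequence")
        n_dam = row.get("n_damaging", 0) or 0
        n_pred = row.get("n_predictions", 0) or 0
        if n_pred > 0 and n_dam > n_pred / 2:
            src.append("prediction-majority")
        flags.append(bool(src))
        sources.append(",".join(src))
    df["oncogenic"] = flags
    df["oncogenic_source"] = sources
    return df


def run_sieve(tables: Mapping[str, pd.DataFrame]) -> dict:
    """Full cascade: merge, quality filters, somatic selection, oncogenic flags."""
    merged = merge_caller_calls(tables)
    if merged.empty:
        return {"merged": merged, "qc_pass": merged, "qc_fail": merged,
                "somatic": merged, "somatic_fail": merged}
    qc_pass, qc_fail = apply_quality_filters(merged)
    somatic, somatic_fail = select_somatic(qc_pass)
    somatic = flag_oncogenic(somatic)
    return {"merged": merged, "qc_pass": qc_pass, "qc_fail": qc_fail,
            "somatic": somatic, "somatic_fail": somatic_fail}


# ---------------------------------------------------------------------------
# fusion majority voting
# ---------------------------------------------------------------------------

def fusion_majority_vote(
    fusion_table: pd.DataFrame,
    min_tools: int = 3,
    artifact_db: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-sample fusion majority vote after artifact-database exclusion.

    ``fusion_table`` rows are (sample, gene5, gene3, tool). Fusions in
    ``artifact_db`` are removed before voting; survivors with >=
    ``min_tools`` distinct supporting tools are kept and merged into a
    cohort master list with per-sample support.
    """
    artifact_db = artifact_db or set()
    df = fusion_table.copy()
    df = df[~df.apply(lambda r: (r["gene5"], r["gene3"]) in artifact_db, axis=1)]
    if df.empty:
        return pd.DataFrame(columns=["sample", "gene5", "gene3", "n_tools", "tools"])
    grouped = (
        df.groupby(["sample", "gene5", "gene3"])["tool"]
        .agg(lambda t: sorted(set(t)))
        .reset_index()
    )
    grouped["n_tools"] = grouped["tool"].str.len()
    grouped["tools"] = grouped["tool"].apply(",".join)
    kept = grouped[grouped["n_tools"] >= min_tools].drop(columns="tool")
    return kept.reset_index(drop=True)
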