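"""Genomic feature catalogs: CpG islands, promoters, enhancers, peak classes.

All coordinates are 0-based, half-open throughout the package. The CpG island
detector follows the classic Gardiner-Garden & Frommer criteria (200 bp
windows, GC > 0.5, observed/expected CpG > 0.6) with a 1 bp sliding step,
merging of overlapping qualifying windows and a re-test of every merged
region against the same criteria.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class FeatureCatalog:
    """Promoter / enhancer / CGI catalogs with per-feature provenance."""

    promoters: list[GenomicInterval] = field(default_factory=list)
    enhancers: list[GenomicInterval] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    provenance: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a``'s width covered by ``b`` (0 when disjoint)."""
    return overlap_length(a, b) / a.width


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: maximal merged runs per chromosome, sorted."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # half-open: abutting intervals stay separate
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def build_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def tree_overlaps(trees: Mapping[str, IntervalTree], iv: GenomicInterval) -> list[GenomicInterval]:
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def union_overlap_length(trees: Mapping[str, IntervalTree], iv: GenomicInterval) -> int:
    """Length of iv covered by the union of tree intervals."""
    hits = sorted(
        (max(iv.start, h.begin), min(iv.end, h.end))
        for h in (trees.get(iv.chrom).overlap(iv.start, iv.end) if iv.chrom in trees else [])
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in hits:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

def _window_stats(c_cum, g_cum, cpg_cum, start, end):
    length = end - start
    n_c = int(c_cum[end] - c_cum[start])
    n_g = int(g_cum[end] - g_cum[start])
    # CpG dinucleotides fully inside [start, end)
    n_cpg = int(cpg_cum[end - 1] - cpg_cum[start]) if end - 1 > start else 0
    gc = (n_c + n_g) / length
    expected = n_c * n_g / length
    oe = n_cpg / expected if expected > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    sequence: str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    chrom: str = "seq",
) -> list[GenomicInterval]:
    """CpG islands by the Gardiner-Garden & Frommer criteria.

    Maximal merged regions of length >= ``min_length`` whose sliding
    ``min_length`` bp windows have GC fraction > ``min_gc`` and
    observed/expected CpG ratio > ``min_oe``, with expected CpG =
    (#C x #G) / window length. ``N`` bases are excluded from all counts.
    Merged regions are re-tested against the same GC and O/E thresholds.
    """
    seq = sequence.upper()
    if not seq:
        return []
    if set(seq) - VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"invalid bases in sequence: {bad}")
    n = len(seq)
    if n < min_length:
        return []

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    c_cum = np.concatenate([[0], np.cumsum(is_c)])
    g_cum = np.concatenate([[0], np.cumsum(is_g)])
    cpg_cum = np.concatenate([[0], np.cumsum(is_cpg)])

    L = min_length
    starts = np.arange(0, n - L + 1)
    n_c = c_cum[starts + L] - c_cum[starts]
    n_g = g_cum[starts + L] - g_cum[starts]
    n_cpg = cpg_cum[starts + L - 1] - cpg_cum[starts]
    gc_frac = (n_c + n_g) / L
    expected = n_c * n_g / L
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, n_cpg / np.where(expected > 0, expected, 1), 0.0)
    qualifies = (gc_frac > min_gc) & (oe > min_oe)

    q_starts = starts[qualifies]
    if q_starts.size == 0:
        return []

    # group qualifying windows whose spans overlap (start gap < L)
    breaks = np.where(np.diff(q_starts) >= L)[0]
    group_bounds = np.split(q_starts, breaks + 1)

    islands: list[GenomicInterval] = []
    for grp in group_bounds:
        s, e = int(grp[0]), int(grp[-1]) + L
        gc, oe_val = _window_stats(c_cum, g_cum, cpg_cum, s, e)
        if gc > min_gc and oe_val > min_oe:
            islands.append(GenomicInterval(chrom, s, e))
    return islands


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def define_promoters_window(
    tss_list: Sequence[tuple[str, str, int, str]],
    upstream: int = 1500,
    downstream: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows around TSS.

    ``tss_list`` holds (gene_id, chrom, tss_position, strand) tuples. The
    window spans ``upstream`` bp upstream and ``downstream`` bp downstream of
    the TSS in transcript orientation, clipped to chromosome bounds.
    """
    out = []
    for gene_id, chrom, tss, strand in tss_list:
        if strand == "+":
            s, e = tss - upstream, tss + downstream
        elif strand == "-":
            s, e = tss - downstream, tss + upstream
        else:
            raise ValueError(f"TSS for {gene_id} lacks a strand")
        s = max(0, s)
        if chrom_lengths is not None:
            e = min(e, chrom_lengths[chrom])
        if e <= s:
            continue
        out.append(GenomicInterval(chrom, s, e, strand, gene_id))
    return sorted(out)


# ---------------------------------------------------------------------------
# enhancer catalog
# ---------------------------------------------------------------------------

def _recurrent_regions(
    peaksets: Sequence[Sequence[GenomicInterval]], min_recurrence: int
) -> list[GenomicInterval]:
    """Merged union regions supported by >= min_recurrence distinct samples."""
    merged = merge_intervals(iv for peaks in peaksets for iv in peaks)
    sample_trees = [build_tree(peaks) for peaks in peaksets]
    out = []
    for region in merged:
        support = sum(1 for t in sample_trees if tree_overlaps(t, region))
        if support >= min_recurrence:
            out.append(region)
    return out


def build_enhancer_catalog(
    h3k27ac_peaksets: Sequence[Sequence[GenomicInterval]],
    atac_peaksets: Sequence[Sequence[GenomicInterval]],
    cage_enhancers: Sequence[GenomicInterval],
    tss_list: Sequence[tuple[str, str, int, str]],
    min_recurrence: int = 3,
    tss_pad: int = 1000,
    max_tss_overlap_frac: float = 0.05,
) -> tuple[list[GenomicInterval], dict[str, dict]]:
    """Consensus enhancer catalog.

    Keeps merged H3K27ac regions present in >= ``min_recurrence`` samples
    that (a) overlap TSS +/- ``tss_pad`` windows by less than
    ``max_tss_overlap_frac`` of their width (>= threshold excludes), (b)
    overlap a recurrent open-chromatin region, and (c) overlap a CAGE
    enhancer. Returns the catalog with per-region provenance.
    """
    if not h3k27ac_peaksets or all(len(p) == 0 for p in h3k27ac_peaksets):
        warnings.warn("no H3K27ac peaks supplied; empty enhancer catalog")
        return [], {}

    recurrent_k27 = _recurrent_regions(h3k27ac_peaksets, min_recurrence)
    recurrent_atac = _recurrent_regions(atac_peaksets, min_recurrence) if atac_peaksets else []
    atac_trees = build_tree(recurrent_atac)
    cage_trees = build_tree(cage_enhancers)

    tss_windows = [
        GenomicInterval(chrom, max(0, pos - tss_pad), pos + tss_pad)
        for _, chrom, pos, _ in tss_list
    ]
    tss_trees = build_tree(tss_windows)

    catalog: list[GenomicInterval] = []
    provenance: dict[str, dict] = {}
    for i, region in enumerate(recurrent_k27):
        tss_frac = union_overlap_length(tss_trees, region) / region.width
        if tss_frac >= max_tss_overlap_frac:
            continue
        has_atac = bool(tree_overlaps(atac_trees, region))
        has_cage = bool(tree_overlaps(cage_trees, region))
        if not (has_atac and has_cage):
            continue
        rid = f"enh_{i}"
        iv = GenomicInterval(region.chrom, region.start, region.end, ".", rid)
        catalog.append(iv)
        provenance[rid] = {
            "rule": "H3K27ac_recurrent+ATAC+CAGE-TSS",
            "tss_overlap_frac": tss_frac,
        }
    return catalog, provenance


def classify_atac_peaks(
    atac_peaks: Sequence[GenomicInterval],
    tss_list: Sequence[tuple[str, str, int, str]],
    promoter_halfwidth: int = 500,
) -> list[str]:
    """Label each peak 'promoter' (>=1 bp overlap with TSS +/- halfwidth) or 'enhancer'."""
    windows = [
        GenomicInterval(chrom, max(0, pos - promoter_halfwidth), pos + promoter_halfwidth)
        for _, chrom, pos, _ in tss_list
    ]
    trees = build_tree(windows)
    return [
        "promoter" if tree_overlaps(trees, peak) else "enhancer" for peak in atac_peaks
    ]
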