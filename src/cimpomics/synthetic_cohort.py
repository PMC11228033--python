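"""Synthetic multi-omics cohort generator for CIMP / AML / T-ALL / HSPC groups.

Generates a self-contained cohort with planted, parameterized effects so
every downstream stage (feature catalogs, consensus differential analysis,
methylation-expression integration, motif activity, CTCF-methylation
coupling, Hi-C linkage, variant sieving) is testable without external data.

Planted structure and its switches:

* ``effect_log2fc`` — discrete silencing effects. For a fraction
  ``frac_silenced_tfs`` of TF genes, the CIMP group gets promoter
  methylation-enrichment means multiplied by ``2**|effect|`` and expression
  means divided by ``2**|effect|``; the motif-activity layer, enhancer
  accessibility of silenced genes, differential loops/TADs and EP-loop to
  expression coupling are all gated on this being non-zero.
* ``meth_expr_rho`` — continuous promoter-methylation vs expression
  coupling. Per-gene latent effects give the true log2 fold changes exactly
  this correlation; 0 disables the layer entirely.
* ``ctcf_coupling_beta`` — methylation sensitivity of CTCF binding. CTCF
  site count means are scaled by ``2*sigmoid(-beta*m)`` (neutral at beta=0
  or m=0) only at sites carrying a CpG at motif position 5 or 15;
  hypermethylation of CTCF sites in CIMP is planted only when beta > 0.
* ``loop_ctcf_coupling`` — probability that a lost loop is anchored at a
  CTCF site from the lost set.

All counts are negative binomial with configurable dispersion; library
scales are log-uniform and rescaled to span exactly [1, 3]x.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as cio
from .features import GenomicInterval
from .quantify import CountMatrix, PeakSet

GROUPS = ("CIMP", "AML", "T-ALL", "HSPC")
CTCF_MOTIF_LENGTH = 19
# CpG-free backbone except at the two planted positions (5 and 15, 1-based)
CTCF_CONSENSUS = "CCAGTAGGGGGCACTAGTT"
BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CIMP": 9, "AML": 20, "T-ALL": 15, "HSPC": 3}
    )
    n_genes: int = 800
    n_regions: dict[str, int] = field(
        default_factory=lambda: {"meth": 1000, "atac": 1100, "h3k27ac": 700, "ctcf": 500}
    )
    genome_length: int = 20_000_000
    nb_dispersion: float = 0.1
    effect_log2fc: float = -3.0
    frac_silenced_tfs: float = 0.3
    ctcf_coupling_beta: float = 4.0
    loop_ctcf_coupling: float = 0.7
    meth_expr_rho: float = -0.3

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"n_per_group[{g}] must be > 0")
        for assay, n in self.n_regions.items():
            if n <= 0:
                raise ValueError(f"n_regions[{assay}] must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.frac_silenced_tfs <= 1:
            raise ValueError("frac_silenced_tfs must be in [0, 1]")
        if not 0 <= self.loop_ctcf_coupling <= 1:
            raise ValueError("loop_ctcf_coupling must be in [0, 1]")
        if self.ctcf_coupling_beta < 0:
            raise ValueError("ctcf_coupling_beta must be >= 0")
        if not -1 <= self.meth_expr_rho <= 0:
            raise ValueError("meth_expr_rho must be in [-1, 0]")
        if self.genome_length < self.n_genes * 6000:
            raise ValueError(
                "genome_length too small: need >= 6 kb per gene "
                f"({self.n_genes * 6000} bp for {self.n_genes} genes)"
            )


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    id: str
    chrom: str
    tss: int
    strand: str
    is_tf: bool
    is_hematopoietic: bool


@dataclass
class CtcfSite:
    id: str
    interval: GenomicInterval
    motif_seq: str
    has_cpg_5: bool
    has_cpg_15: bool


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]]
    genes: list[Gene]
    cgi_truth: list[GenomicInterval]
    ctcf_sites: list[CtcfSite]
    enhancer_truth: list[tuple[GenomicInterval, str]]
    tad_truth: list[GenomicInterval]
    loop_truth: list[dict]  # id, anchor1, anchor2, type, enhancer_id, gene_id

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gene_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}

    def tss_list(self) -> list[tuple[str, str, int, str]]:
        return [(g.id, g.chrom, g.tss, g.strand) for g in self.genes]

    def to_dict(self) -> dict:
        return {
            "chromosomes": self.chromosomes,
            "genes": [dataclasses.asdict(g) for g in self.genes],
            "cgi_truth": [dataclasses.asdict(iv) for iv in self.cgi_truth],
            "ctcf_sites": [
                {
                    "id": s.id,
                    "interval": dataclasses.asdict(s.interval),
                    "motif_seq": s.motif_seq,
                    "has_cpg_5": s.has_cpg_5,
                    "has_cpg_15": s.has_cpg_15,
                }
                for s in self.ctcf_sites
            ],
            "enhancer_truth": [
                {"interval": dataclasses.asdict(iv), "gene": g}
                for iv, g in self.enhancer_truth
            ],
            "tad_truth": [dataclasses.asdict(iv) for iv in self.tad_truth],
            "loop_truth": [
                {k: (dataclasses.asdict(v) if isinstance(v, GenomicInterval) else v)
                 for k, v in loop.items()}
                for loop in self.loop_truth
            ],
        }

    def serialize(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _ctcf_motif_sequence(rng: np.random.Generator, has5: bool, has15: bool) -> str:
    seq = list(CTCF_CONSENSUS)
    # sprinkle noise, avoiding creation of CpG dinucleotides
    for i in range(len(seq)):
        if rng.random() < 0.1:
            seq[i] = str(rng.choice(BASES))
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "T"
    if has5:
        seq[4], seq[5] = "C", "G"
    if has15:
        seq[14], seq[15] = "C", "G"
    return "".join(seq)


def generate_genome(config: CohortConfig) -> GenomeModel:
    """Deterministically lay out genes, CGIs, CTCF sites, enhancers, TADs, loops."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    len1 = int(config.genome_length * 0.6)
    len2 = config.genome_length - len1
    chromosomes = [("chr1", len1), ("chr2", len2)]

    # genes on a jittered grid, 60/40 split across chromosomes
    genes: list[Gene] = []
    n1 = int(config.n_genes * 0.6)
    counts_per_chrom = [n1, config.n_genes - n1]
    for (chrom, clen), n_c in zip(chromosomes, counts_per_chrom):
        if n_c == 0:
            continue
        spacing = (clen - 20000) // n_c
        if spacing < 5000:
            raise ValueError("genome_length too small to place requested genes")
        for i in range(n_c):
            tss = 10000 + i * spacing + int(rng.integers(0, spacing // 4))
            gid = f"gene_{len(genes):04d}"
            is_tf = rng.random() < 0.25
            is_hem = bool(is_tf and rng.random() < 0.5)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gid, chrom, tss, strand, bool(is_tf), is_hem))

    # CGIs at 60% of promoters
    cgi_truth = []
    for g in genes:
        if rng.random() < 0.6:
            cgi_truth.append(
                GenomicInterval(g.chrom, max(0, g.tss - 300), g.tss + 300, ".", f"cgi_{g.id}")
            )

    # CTCF sites in intergenic space
    clens = dict(chromosomes)
    ctcf_sites: list[CtcfSite] = []
    n_ctcf = config.n_regions.get("ctcf", 500)
    for i in range(n_ctcf):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        pos = int(rng.integers(5000, clens[chrom] - 5000))
        has5 = rng.random() < 0.45
        has15 = rng.random() < 0.45
        seq = _ctcf_motif_sequence(rng, has5, has15)
        iv = GenomicInterval(chrom, pos, pos + CTCF_MOTIF_LENGTH, "+", f"ctcf_{i:04d}")
        ctcf_sites.append(CtcfSite(iv.id, iv, seq, has5, has15))

    # TADs tile each chromosome without overlap
    tad_truth = []
    tad_size = max(config.genome_length // 40, 100_000)
    t = 0
    for chrom, clen in chromosomes:
        start = 0
        while start + tad_size <= clen:
            tad_truth.append(GenomicInterval(chrom, start, start + tad_size, ".", f"tad_{t:03d}"))
            start += tad_size
            t += 1

    def tad_of(chrom: str, pos: int) -> GenomicInterval | None:
        for tad in tad_truth:
            if tad.chrom == chrom and tad.start <= pos < tad.end:
                return tad
        return None

    # enhancers for ~35% of genes, 20-200 kb from the TSS, same TAD if possible
    enhancer_truth = []
    for g in genes:
        if rng.random() >= 0.35:
            continue
        tad = tad_of(g.chrom, g.tss)
        for _ in range(10):
            offset = int(rng.integers(20_000, 200_000)) * (1 if rng.random() < 0.5 else -1)
            pos = g.tss + offset
            if pos < 1000 or pos + 1000 > clens[g.chrom]:
                continue
            if tad is not None and not (tad.start <= pos < tad.end):
                continue
            enhancer_truth.append(
                (GenomicInterval(g.chrom, pos, pos + 800, ".", f"enh_{g.id}"), g.id)
            )
            break

    # loops: EP loops over the enhancer truth; CTCF-CTCF loops within TADs
    loop_truth: list[dict] = []
    half = 2500
    for iv, gid in enhancer_truth:
        g = next(x for x in genes if x.id == gid)
        center_e = (iv.start + iv.end) // 2
        a1 = GenomicInterval(iv.chrom, max(0, center_e - half), center_e + half)
        a2 = GenomicInterval(g.chrom, max(0, g.tss - half), g.tss + half)
        if a1.start > a2.start:
            a1, a2 = a2, a1
        loop_truth.append(
            {"id": f"loop_ep_{gid}", "anchor1": a1, "anchor2": a2, "type": "EP",
             "enhancer_id": iv.id, "gene_id": gid}
        )
    by_tad: dict[str, list[CtcfSite]] = {}
    for s in ctcf_sites:
        tad = tad_of(s.interval.chrom, s.interval.start)
        if tad is not None:
            by_tad.setdefault(tad.id, []).append(s)
    n_cc = 0
    for tad_id in sorted(by_tad):
        sites = by_tad[tad_id]
        if len(sites) < 2:
            continue
        pair = rng.choice(len(sites), size=2, replace=False)
        s1, s2 = sites[pair[0]], sites[pair[1]]
        c1 = (s1.interval.start + s1.interval.end) // 2
        c2 = (s2.interval.start + s2.interval.end) // 2
        if c1 > c2:
            s1, s2, c1, c2 = s2, s1, c2, c1
        if c2 - c1 < 2 * half + 1000:
            continue
        a1 = GenomicInterval(s1.interval.chrom, max(0, c1 - half), c1 + half)
        a2 = GenomicInterval(s2.interval.chrom, max(0, c2 - half), c2 + half)
        loop_truth.append(
            {"id": f"loop_cc_{n_cc:03d}", "anchor1": a1, "anchor2": a2,
             "type": "CTCF", "ctcf1": s1.id, "ctcf2": s2.id}
        )
        n_cc += 1

    return GenomeModel(chromosomes, genes, cgi_truth, ctcf_sites,
                       enhancer_truth, tad_truth, loop_truth)


# ---------------------------------------------------------------------------
# truth ledger
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    silenced_tf_ids: list[str] = field(default_factory=list)
    hypermethylated_promoter_ids: list[str] = field(default_factory=list)
    lost_ctcf_site_ids: list[str] = field(default_factory=list)
    hypermeth_ctcf_site_ids: list[str] = field(default_factory=list)
    lost_loop_ids: list[str] = field(default_factory=list)
    gained_loop_ids: list[str] = field(default_factory=list)
    enhancer_targets: dict[str, str] = field(default_factory=dict)
    planted_motif_id: str | None = None
    ctcf_methylation: pd.DataFrame | None = None  # site x group methylation level
    variant_truth: pd.DataFrame | None = None
    fusion_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _sample_names(config: CohortConfig) -> tuple[list[str], dict[str, str]]:
    samples, groups = [], {}
    for grp in GROUPS:
        for i in range(config.n_per_group.get(grp, 0)):
            name = f"{grp}_{i:02d}"
            samples.append(name)
            groups[name] = grp
    return samples, groups


def _library_scales(rng: np.random.Generator, n: int) -> np.ndarray:
    scales = np.exp(rng.uniform(np.log(1.0), np.log(3.0), size=n))
    if n >= 2:  # force an exact 3-fold span so TMM is never trivial
        lo, hi = scales.min(), scales.max()
        scales = 1.0 + (scales - lo) * (3.0 - 1.0) / max(hi - lo, 1e-9)
    return scales


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, bundled."""

    config: CohortConfig
    genome: GenomeModel
    groups: dict[str, str]
    assays: dict[str, CountMatrix]
    expression: CountMatrix
    region_index: dict[str, list[GenomicInterval]]  # assay -> feature intervals
    peaksets: dict[str, list[PeakSet]]
    peak_sequences: dict[str, str]  # atac peak id -> sequence
    pwms: list  # Bio.motifs.Motif
    tad_scores: pd.DataFrame
    loop_scores: pd.DataFrame
    variant_tables: dict[str, pd.DataFrame]
    fusion_tables: pd.DataFrame
    ledger: TruthLedger


def simulate_counts(genome: GenomeModel, config: CohortConfig):
    """Simulate all count matrices and the truth ledger.

    Returns (assays: dict of CountMatrix, expression: CountMatrix, ledger,
    extras) where extras carries region indices, peak sets, sequences, PWMs
    and Hi-C score tables.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    samples, groups = _sample_names(config)
    n_s = len(samples)
    sample_group = np.array([groups[s] for s in samples])
    is_cimp = sample_group == "CIMP"
    scales = _library_scales(rng, n_s)
    disp = config.nb_dispersion
    eff = abs(config.effect_log2fc)
    effects_on = config.effect_log2fc != 0
    rho = config.meth_expr_rho
    ledger = TruthLedger()
    ledger.enhancer_targets = {iv.id: gid for iv, gid in genome.enhancer_truth}

    genes = genome.genes
    gene_ids = [g.id for g in genes]
    cgi_genes = {iv.id.replace("cgi_", "") for iv in genome.cgi_truth}

    # --- planted gene-level effects ---------------------------------------
    tf_ids = [g.id for g in genes if g.is_tf and g.id in cgi_genes]
    n_sil = int(round(config.frac_silenced_tfs * len(tf_ids)))
    silenced = list(rng.choice(tf_ids, size=n_sil, replace=False)) if (
        effects_on and n_sil
    ) else []
    ledger.silenced_tf_ids = sorted(silenced)
    silenced_set = set(silenced)

    # continuous coupled layer (exactly rho-correlated true log2 fold changes)
    meth_delta = np.zeros(len(genes))
    expr_delta = np.zeros(len(genes))
    if rho != 0:
        sigma = 1.5
        u = rng.standard_normal(len(genes))
        v = rng.standard_normal(len(genes))
        meth_delta = sigma * u
        expr_delta = sigma * (rho * u + np.sqrt(1 - rho ** 2) * v)

    # --- expression --------------------------------------------------------
    base_expr = np.exp(rng.normal(np.log(150), 0.8, size=len(genes)))
    expr_mean = np.tile(base_expr[:, None], (1, n_s)).astype(float)
    for gi, g in enumerate(genes):
        fold = 2.0 ** expr_delta[gi]
        if g.id in silenced_set:
            fold /= 2.0 ** eff
        expr_mean[gi, is_cimp] *= fold

    # EP-loop coupling: differential EP loops drag their contacted gene along
    ep_loops = [l for l in genome.loop_truth if l["type"] == "EP"]
    cc_loops = [l for l in genome.loop_truth if l["type"] == "CTCF"]
    loop_delta: dict[str, float] = {}
    if effects_on:
        for loop in ep_loops:
            if rng.random() < 0.5:
                d = float(rng.normal(0, 1.5))
                loop_delta[loop["id"]] = d
                gi = gene_ids.index(loop["gene_id"])
                expr_mean[gi, is_cimp] *= 2.0 ** (0.8 * d)

    # --- CTCF sites: methylation level and binding -------------------------
    sites = genome.ctcf_sites
    beta = config.ctcf_coupling_beta
    m_base = rng.uniform(0.0, 0.2, size=len(sites))
    m_by_group = {grp: m_base.copy() for grp in GROUPS}
    hyper_sites: list[str] = []
    lost_sites: list[str] = []
    if beta > 0:
        for i, s in enumerate(sites):
            flagged = s.has_cpg_5 or s.has_cpg_15
            p_hyper = 0.5 if flagged else 0.2
            if rng.random() < p_hyper:
                m_by_group["CIMP"][i] = rng.uniform(0.6, 1.0)
                hyper_sites.append(s.id)
                if flagged:
                    lost_sites.append(s.id)
    ledger.hypermeth_ctcf_site_ids = sorted(hyper_sites)
    ledger.lost_ctcf_site_ids = sorted(lost_sites)
    ledger.ctcf_methylation = pd.DataFrame(
        m_by_group, index=[s.id for s in sites]
    )

    def ctcf_scale(site_i: int, grp: str) -> float:
        s = sites[site_i]
        if not (s.has_cpg_5 or s.has_cpg_15):
            return 1.0
        m = m_by_group[grp][site_i]
        return 2.0 / (1.0 + np.exp(beta * m))

    base_ctcf = np.exp(rng.normal(np.log(120), 0.6, size=len(sites)))
    ctcf_mean = np.empty((len(sites), n_s))
    for j, grp in enumerate(sample_group):
        for i in range(len(sites)):
            ctcf_mean[i, j] = base_ctcf[i] * ctcf_scale(i, grp)

    # --- loop effects: every lost loop gets, with probability
    # loop_ctcf_coupling, an anchor CTCF site from the lost set -------------
    lost_loops: list[str] = []
    gained_loops: list[str] = []
    loop_fold: dict[str, float] = {}
    if effects_on:
        site_by_id = {s.id: s for s in sites}
        cc_used = set()
        for loop in cc_loops:
            cc_used.update((loop.get("ctcf1"), loop.get("ctcf2")))
        free_lost = [sid for sid in ledger.lost_ctcf_site_ids if sid not in cc_used]
        unchanged_sites = [s.id for s in sites
                           if s.id not in set(hyper_sites) and s.id not in cc_used]
        for loop in cc_loops:
            u = rng.random()
            if u < 0.3:  # lost in CIMP
                lost_loops.append(loop["id"])
                loop_fold[loop["id"]] = 0.25
                pool = (free_lost if (free_lost and
                                      rng.random() < config.loop_ctcf_coupling)
                        else unchanged_sites)
                if pool:
                    sid = pool.pop(int(rng.integers(len(pool))))
                    _reanchor(loop, sid, sites)
            elif u < 0.55:  # gained in CIMP
                gained_loops.append(loop["id"])
                loop_fold[loop["id"]] = 4.0
                if unchanged_sites:
                    sid = unchanged_sites.pop(int(rng.integers(len(unchanged_sites))))
                    _reanchor(loop, sid, sites)
        for loop in ep_loops:
            d = loop_delta.get(loop["id"])
            if d is None:
                continue
            loop_fold[loop["id"]] = 2.0 ** d
            if d < -1:
                lost_loops.append(loop["id"])
                if free_lost and rng.random() < config.loop_ctcf_coupling:
                    # relocate an unused lost CTCF site into the enhancer anchor
                    sid = free_lost.pop(int(rng.integers(len(free_lost))))
                    site = site_by_id[sid]
                    a1 = loop["anchor1"]
                    c = (a1.start + a1.end) // 2
                    site.interval = GenomicInterval(
                        a1.chrom, c, c + CTCF_MOTIF_LENGTH, "+", sid
                    )
            elif d > 1:
                gained_loops.append(loop["id"])
    ledger.lost_loop_ids = sorted(lost_loops)
    ledger.gained_loop_ids = sorted(gained_loops)

    # --- methylation (MCIP-like enrichment counts) -------------------------
    meth_regions: list[GenomicInterval] = []
    meth_mean_rows: list[np.ndarray] = []
    hyper_promoters: list[str] = []
    clens = genome.chrom_lengths()
    for gi, g in enumerate(genes):
        if g.id not in cgi_genes:
            continue
        rid = f"meth_prom_{g.id}"
        meth_regions.append(
            GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500, ".", rid)
        )
        base = np.exp(rng.normal(np.log(80), 0.6))
        row = np.full(n_s, base)
        fold = 2.0 ** meth_delta[gi]
        if g.id in silenced_set:
            fold *= 2.0 ** eff
            hyper_promoters.append(rid)
        row[is_cimp] *= fold
        meth_mean_rows.append(row)
    ledger.hypermethylated_promoter_ids = sorted(hyper_promoters)

    covered = rng.random(len(sites)) < 0.6  # MCIP covers a fraction of CTCF sites
    for i, s in enumerate(sites):
        if not covered[i]:
            continue
        rid = f"meth_ctcf_{s.id}"
        iv = s.interval
        meth_regions.append(
            GenomicInterval(iv.chrom, max(0, iv.start - 300), iv.end + 300, ".", rid)
        )
        base = np.exp(rng.normal(np.log(60), 0.5))
        row = np.array([
            base * 2.0 ** (3.0 * (m_by_group[grp][i] - m_base[i]))
            for grp in sample_group
        ])
        meth_mean_rows.append(row)

    n_bg_meth = max(config.n_regions.get("meth", 1000) - len(meth_regions), 0)
    for k in range(n_bg_meth):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        pos = int(rng.integers(1000, clens[chrom] - 2000))
        meth_regions.append(GenomicInterval(chrom, pos, pos + 600, ".", f"meth_bg_{k:04d}"))
        meth_mean_rows.append(np.full(n_s, np.exp(rng.normal(np.log(60), 0.6))))

    # --- ATAC: promoter peaks, enhancer peaks, motif-planted background ----
    atac_regions: list[GenomicInterval] = []
    atac_mean_rows: list[np.ndarray] = []
    # correlated enhancer/promoter latent noise per gene with an enhancer
    enh_targets = ledger.enhancer_targets
    eta = {gid: rng.normal(0, 0.5, size=n_s)
           for gid in sorted(set(enh_targets.values()))}
    for gi, g in enumerate(genes):
        rid = f"atac_prom_{g.id}"
        atac_regions.append(
            GenomicInterval(g.chrom, max(0, g.tss - 150), g.tss + 150, ".", rid)
        )
        base = np.exp(rng.normal(np.log(100), 0.5))
        row = np.full(n_s, base)
        if g.id in eta:
            row = row * 2.0 ** eta[g.id]
        if g.id in silenced_set:
            row[is_cimp] /= 2.0 ** (eff / 2.0)
        atac_mean_rows.append(row)
    for iv, gid in genome.enhancer_truth:
        rid = f"atac_enh_{gid}"
        atac_regions.append(GenomicInterval(iv.chrom, iv.start, iv.end, ".", rid))
        base = np.exp(rng.normal(np.log(90), 0.5))
        row = base * 2.0 ** eta[gid]
        if gid in silenced_set:
            row = row.copy()
            row[is_cimp] /= 2.0 ** (eff / 2.0)
        gi = gene_ids.index(gid)
        if expr_delta[gi] != 0:
            row = row * 2.0 ** (0.6 * expr_delta[gi] * is_cimp)
        atac_mean_rows.append(row)

    # synthetic PWMs; motif 0 is the planted "active" motif
    pwms, consensus_list = _make_pwms(rng, n_motifs=8)
    planted_consensus = consensus_list[0]
    ledger.planted_motif_id = pwms[0].matrix_id if effects_on else None
    activity = np.where(is_cimp, 1.0, 0.0) + rng.normal(0, 0.15, size=n_s)

    n_bg_atac = max(
        config.n_regions.get("atac", 1100) - len(atac_regions), 40
    )
    peak_sequences: dict[str, str] = {}
    gc_levels = rng.uniform(0.35, 0.65, size=n_bg_atac)
    for k in range(n_bg_atac):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        pos = int(rng.integers(1000, clens[chrom] - 2000))
        rid = f"atac_bg_{k:04d}"
        atac_regions.append(GenomicInterval(chrom, pos, pos + 300, ".", rid))
        base = np.exp(rng.normal(np.log(80), 0.5))
        row = np.full(n_s, base)
        seq = _random_seq(rng, 200, gc_levels[k])
        if effects_on and rng.random() < 0.15:
            ins = int(rng.integers(0, 200 - len(planted_consensus)))
            seq = seq[:ins] + planted_consensus + seq[ins + len(planted_consensus):]
            row = row * 2.0 ** (1.0 * activity)  # group-specific doubling
        peak_sequences[rid] = seq
        atac_mean_rows.append(row)
    # sequences for promoter/enhancer peaks (no planted motif)
    for iv in atac_regions:
        if iv.id not in peak_sequences:
            peak_sequences[iv.id] = _random_seq(rng, 200, 0.5)

    # planted TF gene expression tracks its motif activity
    if effects_on:
        tf_act_gene = gene_ids[0]
        gi = 0
        expr_mean[gi, :] = base_expr[gi] * 2.0 ** (1.5 * activity)
        ledger_planted_gene = tf_act_gene
    else:
        ledger_planted_gene = None

    # --- H3K27ac: enhancer regions + background ----------------------------
    k27_regions: list[GenomicInterval] = []
    k27_mean_rows: list[np.ndarray] = []
    for iv, gid in genome.enhancer_truth:
        rid = f"k27_enh_{gid}"
        k27_regions.append(GenomicInterval(iv.chrom, iv.start, iv.end, ".", rid))
        base = np.exp(rng.normal(np.log(110), 0.5))
        row = np.full(n_s, base)
        if gid in silenced_set:
            row = row.copy()
            row[is_cimp] /= 2.0 ** (eff / 2.0)
        k27_mean_rows.append(row)
    n_bg_k27 = max(config.n_regions.get("h3k27ac", 700) - len(k27_regions), 20)
    for k in range(n_bg_k27):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        pos = int(rng.integers(1000, clens[chrom] - 2000))
        k27_regions.append(GenomicInterval(chrom, pos, pos + 700, ".", f"k27_bg_{k:04d}"))
        k27_mean_rows.append(np.full(n_s, np.exp(rng.normal(np.log(90), 0.5))))

    # --- Hi-C scores --------------------------------------------------------
    loop_ids = [l["id"] for l in genome.loop_truth]
    base_loop = np.exp(rng.normal(np.log(200), 0.4, size=len(loop_ids)))
    loop_mean = np.tile(base_loop[:, None], (1, n_s)).astype(float)
    for li, lid in enumerate(loop_ids):
        if lid in loop_fold:
            loop_mean[li, is_cimp] *= loop_fold[lid]

    tad_ids = [tad.id for tad in genome.tad_truth]
    base_tad = np.exp(rng.normal(np.log(300), 0.3, size=len(tad_ids)))
    tad_mean = np.tile(base_tad[:, None], (1, n_s)).astype(float)
    if effects_on:
        n_dtad = max(len(tad_ids) // 5, 1)
        dtads = rng.choice(len(tad_ids), size=n_dtad, replace=False)
        for ti in dtads:
            tad_mean[ti, is_cimp] *= 2.0 ** float(rng.normal(0, 1.2))

    # --- draw counts --------------------------------------------------------
    def draw(mean_rows, regions) -> pd.DataFrame:
        mean = np.vstack(mean_rows) * scales[None, :]
        counts = _nb_draw(rng, mean, disp)
        return pd.DataFrame(counts, index=[iv.id for iv in regions], columns=samples)

    meth_df = draw(meth_mean_rows, meth_regions)
    atac_df = draw(atac_mean_rows, atac_regions)
    k27_df = draw(k27_mean_rows, k27_regions)
    ctcf_df = pd.DataFrame(
        _nb_draw(rng, ctcf_mean * scales[None, :], disp),
        index=[f"ctcfpk_{s.id}" for s in sites], columns=samples,
    )
    expr_df = pd.DataFrame(
        _nb_draw(rng, expr_mean * scales[None, :], disp),
        index=gene_ids, columns=samples,
    )
    tad_df = pd.DataFrame(
        _nb_draw(rng, tad_mean * scales[None, :], disp), index=tad_ids, columns=samples
    )
    loop_df = pd.DataFrame(
        _nb_draw(rng, loop_mean * scales[None, :], disp), index=loop_ids, columns=samples
    )

    ctcf_regions = [
        GenomicInterval(s.interval.chrom, max(0, s.interval.start - 400),
                        s.interval.end + 400, ".", f"ctcfpk_{s.id}")
        for s in sites
    ]

    assays = {
        "meth": CountMatrix(meth_df, dict(groups)),
        "atac": CountMatrix(atac_df, dict(groups)),
        "h3k27ac": CountMatrix(k27_df, dict(groups)),
        "ctcf": CountMatrix(ctcf_df, dict(groups)),
    }
    expression = CountMatrix(expr_df, dict(groups))
    region_index = {
        "meth": meth_regions, "atac": atac_regions,
        "h3k27ac": k27_regions, "ctcf": ctcf_regions,
    }

    # --- per-sample peak sets ----------------------------------------------
    peaksets: dict[str, list[PeakSet]] = {}
    for assay in ("meth", "atac", "h3k27ac", "ctcf"):
        mat = assays[assay].matrix
        regions = region_index[assay]
        med = np.median(mat.to_numpy(), axis=1)
        psets = []
        for j, sample in enumerate(samples):
            col = mat.iloc[:, j].to_numpy()
            active = col > 0.5 * np.maximum(med, 1)
            present = rng.random(len(regions)) < np.where(active, 0.92, 0.15)
            sig = np.where(
                rng.random(len(regions)) < 0.05,
                rng.uniform(2, 9, size=len(regions)),
                rng.uniform(11, 60, size=len(regions)),
            )
            rows = [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "neglog10q": float(sig[i])}
                for i, iv in enumerate(regions) if present[i]
            ]
            psets.append(PeakSet(sample, pd.DataFrame(
                rows, columns=["chrom", "start", "end", "neglog10q"])))
        peaksets[assay] = psets

    extras = {
        "region_index": region_index,
        "peaksets": peaksets,
        "peak_sequences": peak_sequences,
        "pwms": pwms,
        "tad_scores": tad_df,
        "loop_scores": loop_df,
        "planted_activator_gene": ledger_planted_gene,
        "library_scales": dict(zip(samples, scales)),
    }
    return assays, expression, ledger, extras


def _reanchor(loop: dict, site_id: str, sites) -> None:
    """Move anchor1 of a CTCF loop onto the given site (keeps anchor order)."""
    site = next(s for s in sites if s.id == site_id)
    c = (site.interval.start + site.interval.end) // 2
    half = 2500
    loop["ctcf1"] = site_id
    loop["anchor1"] = GenomicInterval(site.interval.chrom, max(0, c - half), c + half)
    if loop["anchor1"].start > loop["anchor2"].start:
        loop["anchor1"], loop["anchor2"] = loop["anchor2"], loop["anchor1"]
        loop["ctcf1"], loop["ctcf2"] = loop.get("ctcf2"), loop.get("ctcf1")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _make_pwms(rng: np.random.Generator, n_motifs: int = 8):
    """Synthetic JASPAR-style motifs with strong consensus positions."""
    from Bio import motifs as bio_motifs

    pwms = []
    consensus_list = []
    for m in range(n_motifs):
        length = int(rng.integers(8, 13))
        cons_idx = rng.choice(4, size=length)
        counts = {b: [] for b in "ACGT"}
        for i in range(length):
            col = np.full(4, 4.0)
            col[cons_idx[i]] = 88.0
            for k, b in enumerate("ACGT"):
                counts[b].append(float(col[k]))
        motif = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        motif.matrix_id = f"SYN{m:03d}"
        motif.name = f"TFSYN{m}"
        pwms.append(motif)
        consensus_list.append("".join("ACGT"[i] for i in cons_idx))
    return pwms, consensus_list


# ---------------------------------------------------------------------------
# variant and fusion tables
# ---------------------------------------------------------------------------

CALLERS = ("haplotypecaller", "mutect2", "varscan2", "bcftools", "strelka2", "pindel")
FUSION_TOOLS = ("star-fusion", "fusioncatcher", "arriba", "pizzly", "jaffa", "squid")
CH_GENES = ("DNMT3A", "TET2", "ASXL1")

_VARIANT_DEFAULTS = dict(
    type="SNV", depth_total=100, depth_alt=30, strand_bias=0.5,
    mapping_quality=60.0, base_quality=35.0, other_allele_fraction=0.05,
    alt_alignment_fraction=0.02, indel_length=0, in_capture_pad200=True,
    in_simple_repeat=False, in_selfchain95=False,
    exonic_func="nonsynonymous SNV", region_func="exonic",
    popfreq=0.0, cosmic_heme_count=0, in_cosmic=False, gene="GENEX",
    in_donor_set=False, in_panel_blacklist=False,
    n_damaging=2, n_predictions=7,
)


def simulate_variant_tables(genome: GenomeModel, config: CohortConfig):
    """Multi-caller variant tables covering every filter-rule branch.

    Returns (per-caller tables, fusion tables, ledger entries). Each planted
    variant's expected verdict (qc_pass / somatic / oncogenic plus the first
    failing rule) is recorded by construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    rows: list[dict] = []
    pos_counter = [10_000]

    def add(expected_fail: str | None, somatic: bool = True, oncogenic: bool = False,
            n: int = 1, **over):
        for _ in range(n):
            pos_counter[0] += int(rng.integers(200, 400))
            rec = dict(_VARIANT_DEFAULTS)
            rec.update(chrom="chr1", pos=pos_counter[0], ref="A", alt="G")
            rec.update(over)
            if rec["depth_total"] and rec["depth_alt"] is not None:
                rec["vaf"] = rec["depth_alt"] / rec["depth_total"]
            else:
                rec["vaf"] = None
            rec["expected_fail_rule"] = expected_fail or ""
            rec["expected_qc_pass"] = expected_fail is None or not expected_fail.startswith("qc")
            rec["expected_somatic"] = bool(expected_fail is None and somatic)
            rec["expected_oncogenic"] = bool(rec["expected_somatic"] and oncogenic)
            rows.append(rec)

    # clean passes (several, some oncogenic)
    add(None, n=12)
    add(None, oncogenic=True, in_cosmic=True, n=4)
    add(None, oncogenic=True, exonic_func="stopgain", n=3)
    add(None, oncogenic=True, exonic_func="frameshift insertion", type="insertion",
        ref="A", alt="AT", indel_length=1, n=3)
    add(None, oncogenic=True, n_damaging=5, n_predictions=7, n=3)
    add(None, oncogenic=False, n_damaging=2, n_predictions=7, n=2)

    # quality-cascade fail branches
    add("qc:strand_bias", strand_bias=0.0, n=3)
    add("qc:strand_bias", strand_bias=1.0, n=3)
    add("qc:depth_total", depth_total=7, depth_alt=4, n=3)
    add("qc:depth_alt", depth_total=50, depth_alt=3, n=3)
    add("qc:mapping_quality", mapping_quality=39.0, n=3)
    add("qc:base_quality", base_quality=29.0, n=3)
    add("qc:other_allele_fraction", other_allele_fraction=0.40, n=3)
    add("qc:other_allele_fraction", other_allele_fraction=0.55, n=2)
    add("qc:alt_alignment_fraction", alt_alignment_fraction=0.11, n=3)
    add("qc:indel_length", type="deletion", ref="A" * 501, alt="A",
        indel_length=500, n=3)
    add("qc:simple_repeat", in_simple_repeat=True, n=3)
    add("qc:selfchain", in_selfchain95=True, n=3)
    add("qc:metric-missing", depth_total=None, n=2)
    # strand-bias rule only applies inside the padded capture
    add(None, strand_bias=0.0, in_capture_pad200=False, n=2)

    # SNV cluster branches on a dedicated chromosome
    for p in (100, 103, 107):
        rec = dict(_VARIANT_DEFAULTS)
        rec.update(chrom="chr2", pos=p, ref="A", alt="G", vaf=0.3,
                   expected_fail_rule="qc:snv_cluster", expected_qc_pass=False,
                   expected_somatic=False, expected_oncogenic=False)
        rows.append(rec)
    for p in (200, 203, 208):  # gap of 5 is not < 5: kept
        rec = dict(_VARIANT_DEFAULTS)
        rec.update(chrom="chr2", pos=p, ref="A", alt="G", vaf=0.3,
                   expected_fail_rule="", expected_qc_pass=True,
                   expected_somatic=True, expected_oncogenic=False)
        rows.append(rec)

    # somatic-selection branches
    add("somatic:region", region_func="intronic", n=3)
    add(None, region_func="splicing_acceptor", n=2)
    add("somatic:exonic_func", exonic_func="synonymous SNV", n=3)
    add("somatic:vaf", depth_total=1000, depth_alt=9, n=3)
    add("somatic:popfreq", popfreq=0.001, n=3)
    add(None, popfreq=0.001, cosmic_heme_count=5, in_cosmic=True, oncogenic=True, n=2)
    add(None, popfreq=0.001, cosmic_heme_count=6, in_cosmic=True, oncogenic=True, n=2)
    add("somatic:popfreq", popfreq=0.001, cosmic_heme_count=4, in_cosmic=True, n=2)
    add(None, popfreq=0.001, gene="DNMT3A", n=2)
    add(None, popfreq=0.001, gene="TET2", n=1)
    add(None, popfreq=0.001, gene="ASXL1", n=1)
    add("somatic:donor", in_donor_set=True, n=3)
    add("somatic:blacklist", in_panel_blacklist=True, n=3)

    # filler passes to exceed 200 planted variants
    n_filler = max(0, 210 - len(rows))
    add(None, n=n_filler)

    truth = pd.DataFrame(rows)
    truth.insert(0, "variant_id", [f"var_{i:04d}" for i in range(len(truth))])

    # distribute across callers; every variant seen by >= 1 caller
    caller_tables: dict[str, list[dict]] = {c: [] for c in CALLERS}
    caller_sets = []
    for i in range(len(truth)):
        k = int(rng.integers(1, len(CALLERS) + 1))
        chosen = rng.choice(CALLERS, size=k, replace=False)
        caller_sets.append(sorted(chosen))
        for c in chosen:
            rec = truth.iloc[i].to_dict()
            rec.pop("expected_fail_rule"), rec.pop("expected_qc_pass")
            rec.pop("expected_somatic"), rec.pop("expected_oncogenic")
            caller_tables[c].append(rec)
    truth["callers"] = [",".join(cs) for cs in caller_sets]

    # one event reported in two indel representations by different callers
    shared = dict(_VARIANT_DEFAULTS)
    shared.update(chrom="chr1", pos=900_000, ref="CA", alt="CAA",
                  type="insertion", indel_length=1, vaf=0.3)
    alt_repr = dict(shared)
    alt_repr.update(pos=900_001, ref="A", alt="AA")
    caller_tables["mutect2"].append(dict(shared, variant_id="var_dup_a"))
    caller_tables["pindel"].append(dict(alt_repr, variant_id="var_dup_b"))
    dup = dict(shared)
    dup.update(variant_id="var_dup", callers="mutect2,pindel",
               expected_fail_rule="", expected_qc_pass=True,
               expected_somatic=True, expected_oncogenic=False)
    truth = pd.concat([truth, pd.DataFrame([dup])], ignore_index=True)

    tables = {
        c: pd.DataFrame(t, columns=list(truth.columns.drop(
            ["expected_fail_rule", "expected_qc_pass", "expected_somatic",
             "expected_oncogenic", "callers"])))
        for c, t in caller_tables.items()
    }

    # fusions
    fusion_rows = []
    expected_keep = []
    genes = [g.id for g in genome.genes[:40]]
    for i in range(14):
        g5, g3 = genes[2 * i], genes[2 * i + 1]
        n_tools = (i % 6) + 1
        in_artifact = i % 7 == 0
        tools = list(rng.choice(FUSION_TOOLS, size=n_tools, replace=False))
        for tool in tools:
            fusion_rows.append({"sample": "CIMP_00", "gene5": g5, "gene3": g3,
                                "tool": tool, "in_artifact_db": in_artifact})
        expected_keep.append({"gene5": g5, "gene3": g3, "n_tools": n_tools,
                              "in_artifact_db": in_artifact,
                              "expected_kept": bool(n_tools >= 3 and not in_artifact)})
    fusion_tables = pd.DataFrame(fusion_rows)
    fusion_truth = pd.DataFrame(expected_keep)
    return tables, fusion_tables, truth, fusion_truth


# ---------------------------------------------------------------------------
# top-level convenience + fixture bundle
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    config = config or CohortConfig()
    genome = generate_genome(config)
    assays, expression, ledger, extras = simulate_counts(genome, config)
    tables, fusion_tables, variant_truth, fusion_truth = simulate_variant_tables(
        genome, config
    )
    ledger.variant_truth = variant_truth
    ledger.fusion_truth = fusion_truth
    _, groups = _sample_names(config)
    return SyntheticCohort(
        config=config, genome=genome, groups=groups, assays=assays,
        expression=expression, region_index=extras["region_index"],
        peaksets=extras["peaksets"], peak_sequences=extras["peak_sequences"],
        pwms=extras["pwms"], tad_scores=extras["tad_scores"],
        loop_scores=extras["loop_scores"], variant_tables=tables,
        fusion_tables=fusion_tables, ledger=ledger,
    )


def write_fixture_bundle(cohort: SyntheticCohort, directory: str | Path) -> list[dict]:
    """Write the cohort as plain-text fixtures; returns the manifest entries."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc

    entries: list[dict] = []

    def record(path: Path, fmt: str):
        entries.append({"file": path.name, "format": fmt,
                        "sha256": cio.file_checksum(path)})

    # feature BEDs
    for name, ivs in [
        ("cgi_truth.bed", cohort.genome.cgi_truth),
        ("tads.bed", cohort.genome.tad_truth),
        ("ctcf_sites.bed", [s.interval for s in cohort.genome.ctcf_sites]),
        ("enhancer_truth.bed", [iv for iv, _ in cohort.genome.enhancer_truth]),
    ]:
        p = directory / name
        cio.write_bed(ivs, p)
        record(p, "BED6")

    # loops as BEDPE
    loop_rows = []
    for loop in cohort.genome.loop_truth:
        a1, a2 = loop["anchor1"], loop["anchor2"]
        loop_rows.append({
            "chrom1": a1.chrom, "start1": a1.start, "end1": a1.end,
            "chrom2": a2.chrom, "start2": a2.start, "end2": a2.end,
            "name": loop["id"], "score": 0.0,
        })
    p = directory / "loops.bedpe"
    cio.write_bedpe(pd.DataFrame(loop_rows), p)
    record(p, "BEDPE")

    # count matrices
    for assay, cm in {**cohort.assays, "expression": cohort.expression}.items():
        p = directory / f"counts_{assay}.tsv"
        cio.write_matrix(cm.matrix, p)
        record(p, "TSV")
    for name, df in [("tad_scores.tsv", cohort.tad_scores),
                     ("loop_scores.tsv", cohort.loop_scores)]:
        p = directory / name
        cio.write_matrix(df, p)
        record(p, "TSV")

    # narrowPeak per sample (one assay is enough to exercise the format)
    for ps in cohort.peaksets["atac"]:
        df = ps.peaks.rename(columns={"neglog10q": "qValue"}).copy()
        df["name"] = [f"{ps.sample_id}_pk{i}" for i in range(len(df))]
        p = directory / f"peaks_atac_{ps.sample_id}.narrowPeak"
        cio.write_narrowpeak(df, p)
        record(p, "narrowPeak")

    # sequences
    seqs = {s.id: s.motif_seq for s in cohort.genome.ctcf_sites}
    p = directory / "ctcf_motifs.fasta"
    cio.write_fasta(seqs, p)
    record(p, "FASTA")
    p = directory / "atac_peak_sequences.fasta"
    cio.write_fasta(cohort.peak_sequences, p)
    record(p, "FASTA")

    # PWMs
    p = directory / "motifs.jaspar"
    cio.write_jaspar_pfms(cohort.pwms, p)
    record(p, "JASPAR")

    # variant and fusion tables
    for caller, df in cohort.variant_tables.items():
        p = directory / f"variants_{caller}.tsv"
        df.to_csv(p, sep="\t", index=False)
        record(p, "TSV")
    p = directory / "fusions.tsv"
    cohort.fusion_tables.to_csv(p, sep="\t", index=False)
    record(p, "TSV")

    # sample groups
    p = directory / "samples.tsv"
    pd.Series(cohort.groups, name="group").rename_axis("sample").to_csv(p, sep="\t")
    record(p, "TSV")

    cio.write_manifest(entries, directory / "manifest.json")
    return entries
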