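"""Consensus peak master list and TMM-normalized count matrices.

Per-sample peak sets carry a -log10(q) per peak; only peaks above the
significance floor count as support, support in >= 2 samples is required, and
supported peaks are merged into maximal unions. Counting is matrix-based
(peaks arrive pre-quantified); input-DNA counts are subtracted with a floor
at zero. Normalization uses the trimmed mean of M-values with the sum of
reads in consensus peaks as the library size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import GenomicInterval, build_tree, merge_intervals, tree_overlaps

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """One sample's called peaks with per-peak -log10(q) significance."""

    sample_id: str
    peaks: pd.DataFrame  # columns: chrom, start, end, neglog10q

    def __post_init__(self):
        required = {"chrom", "start", "end", "neglog10q"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"PeakSet {self.sample_id} missing columns {sorted(missing)}")
        if (self.peaks["neglog10q"] < 0).any():
            raise ValueError("peak significance must be >= 0")

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.peaks.itertuples()
        ]


@dataclass
class CountMatrix:
    """Features x samples counts with group labels and normalization slots."""

    matrix: pd.DataFrame  # features x samples, non-negative
    groups: dict[str, str]  # sample id -> group label
    input_counts: pd.DataFrame | None = None
    norm: "NormalizationFactors | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unlabeled = [s for s in self.matrix.columns if s not in self.groups]
        if unlabeled:
            raise ValueError(f"samples without group label: {unlabeled}")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def subset_groups(self, keep: Sequence[str]) -> "CountMatrix":
        cols = [s for s in self.matrix.columns if self.groups[s] in set(keep)]
        return CountMatrix(self.matrix[cols], {s: self.groups[s] for s in cols},
                           meta=dict(self.meta))


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors; geometric mean of factors is 1."""

    factors: dict[str, float]
    library_sizes: dict[str, float]
    logratio_trim: float = 0.30
    sum_trim: float = 0.05
    reference_sample: str | None = None

    @property
    def effective_library_sizes(self) -> dict[str, float]:
        return {s: self.factors[s] * self.library_sizes[s] for s in self.factors}


# ---------------------------------------------------------------------------
# master list
# ---------------------------------------------------------------------------

def build_master_list(
    peaksets: Sequence[PeakSet],
    min_samples: int = 2,
    min_neglog10q: float = 10.0,
    blacklist: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Consensus peak master list.

    Per sample, peaks with -log10(q) <= ``min_neglog10q`` are dropped
    (support requires strictly higher significance) and blacklist-overlapping
    peaks removed. A surviving peak is kept when peaks from >=
    ``min_samples`` distinct samples overlap it by >= 1 bp (itself included);
    kept peaks are merged into maximal unions, sorted and disjoint.
    """
    if len(peaksets) < min_samples:
        raise ValueError(f"need at least {min_samples} peak sets")
    bl_trees = build_tree(blacklist) if blacklist else {}

    filtered: list[list[GenomicInterval]] = []
    for ps in peaksets:
        keep = ps.peaks[ps.peaks["neglog10q"] > min_neglog10q]
        ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in keep.itertuples()]
        if bl_trees:
            ivs = [iv for iv in ivs if not tree_overlaps(bl_trees, iv)]
        filtered.append(ivs)

    sample_trees = [build_tree(ivs) for ivs in filtered]
    supported: list[GenomicInterval] = []
    for ivs in filtered:
        for iv in ivs:
            support = sum(1 for t in sample_trees if tree_overlaps(t, iv))
            if support >= min_samples:
                supported.append(iv)

    if not supported:
        warnings.warn("master list empty after filtering")
        return []
    merged = merge_intervals(supported)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"peak_{i}")
        for i, iv in enumerate(merged)
    ]


# ---------------------------------------------------------------------------
# counting with input subtraction
# ---------------------------------------------------------------------------

def count_with_input_subtraction(
    sample_counts: pd.DataFrame,
    input_counts: pd.DataFrame | None,
    groups: Mapping[str, str],
) -> CountMatrix:
    """Per feature and sample, max(0, sample - input); no input leaves counts as-is."""
    if input_counts is None:
        cm = CountMatrix(sample_counts.copy(), dict(groups))
        cm.meta["input_subtracted"] = False
        return cm
    if not sample_counts.index.equals(input_counts.index) or list(
        sample_counts.columns
    ) != list(input_counts.columns):
        raise ValueError("sample and input count matrices are not aligned")
    sub = (sample_counts - input_counts).clip(lower=0)
    cm = CountMatrix(sub, dict(groups), input_counts=input_counts.copy())
    cm.meta["input_subtracted"] = True
    return cm


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _choose_reference(y: np.ndarray) -> int:
    """Sample whose 75th count percentile (library-scaled) is closest to the mean."""
    lib = y.sum(axis=0)
    f75 = np.array([np.percentile(y[:, j], 75) / lib[j] for j in range(y.shape[1])])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    """TMM factor of obs vs ref (log2 scale returned as linear factor)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = sps_rankdata(m)
    rank_a = sps_rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def sps_rankdata(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)


def tmm_factors(
    counts: CountMatrix,
    reference_sample: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M normalization factors over consensus-peak counts.

    M = log2 ratio and A = mean log2 abundance after library-size scaling,
    computed pairwise against the reference over features non-zero in both
    samples; the stated fractions of extreme M and A are trimmed from each
    tail; the factor is the precision-weighted mean of the remaining M;
    factors are rescaled to geometric mean 1.
    """
    y = counts.matrix.to_numpy(dtype=float)
    samples = counts.samples
    if len(samples) < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = y.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(f"sample with all-zero counts: {samples[zero[0]]}")

    if reference_sample is None:
        ref_j = _choose_reference(y)
    else:
        ref_j = samples.index(reference_sample)

    factors = np.array([
        _tmm_pair(y[:, j], y[:, ref_j], lib[j], lib[ref_j], logratio_trim, sum_trim)
        if j != ref_j else 1.0
        for j in range(len(samples))
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors={s: float(f) for s, f in zip(samples, factors)},
        library_sizes={s: float(v) for s, v in zip(samples, lib)},
        logratio_trim=logratio_trim,
        sum_trim=sum_trim,
        reference_sample=samples[ref_j],
    )
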