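"""Motif scanning and bias-corrected accessibility deviations.

Scanning uses log-odds scores quantized to 1e-3 bits with a match threshold
derived from the exact dynamic-programming distribution of scores under the
background model (target p ~ 5e-5), scanning both strands. Deviations follow
the chromVAR idea: per sample, the observed fraction of reads in
motif-containing peaks is compared to the expectation from the cohort-wide
read distribution, and Z-scored against background peak sets matched on GC
content and mean accessibility (10 x 10 bins, sampled with replacement).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

QUANT = 1000  # log-odds quantization: 1e-3 bits per integer unit
DEFAULT_MATCH_P = 5e-5
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# PWM machinery
# ---------------------------------------------------------------------------

def pwm_probabilities(motif, pseudocount: float = 0.01) -> np.ndarray:
    """Position x base probability matrix from a Bio.motifs Motif."""
    counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float).T
    counts = counts + pseudocount * counts.sum(axis=1, keepdims=True).mean()
    probs = counts / counts.sum(axis=1, keepdims=True)
    return probs


def quantized_logodds(motif, background: np.ndarray | None = None) -> np.ndarray:
    """Integer log2-odds matrix (positions x 4), units of 1/QUANT bits."""
    probs = pwm_probabilities(motif)
    bg = background if background is not None else np.full(4, 0.25)
    lo = np.log2(probs / bg[None, :])
    return np.round(lo * QUANT).astype(np.int64)


def score_distribution(qmat: np.ndarray, background: np.ndarray | None = None):
    """Exact DP distribution of total quantized score under the background.

    Returns (offsets, probabilities): probabilities[i] is the chance of
    total score offsets[i] for a random background k-mer.
    """
    bg = background if background is not None else np.full(4, 0.25)
    lo_min = int(qmat.min(axis=1).sum())
    lo_max = int(qmat.max(axis=1).sum())
    size = lo_max - lo_min + 1
    dist = np.zeros(size)
    # dist over score - (cumulative minimum); start before any position
    dist[0] = 1.0
    cur_min = 0
    for pos in range(qmat.shape[0]):
        row = qmat[pos]
        row_min = int(row.min())
        new = np.zeros(size)
        for b in range(4):
            shift = int(row[b]) - row_min
            if shift < size:
                new[shift:] += bg[b] * dist[: size - shift]
        dist = new
        cur_min += row_min
    offsets = np.arange(size) + cur_min
    return offsets, dist


def match_threshold(qmat: np.ndarray, pvalue: float = DEFAULT_MATCH_P,
                    background: np.ndarray | None = None) -> int:
    """Smallest quantized score t with P(score >= t) <= pvalue."""
    offsets, dist = score_distribution(qmat, background)
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.where((tail <= pvalue) & (dist > 0))[0]  # smallest achievable score
    if ok.size == 0:
        return int(offsets[-1]) + 1  # only the impossible score qualifies
    return int(offsets[ok[0]])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def _scan_one(qmat: np.ndarray, idx: np.ndarray, threshold: int) -> bool:
    k = qmat.shape[0]
    n = idx.size
    if n < k:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return False
    w = windows[valid]
    scores = qmat[np.arange(k)[None, :], w].sum(axis=1)
    return bool((scores >= threshold).any())


def _revcomp_qmat(qmat: np.ndarray) -> np.ndarray:
    return qmat[::-1, ::-1]


def scan_motifs(
    pwms: Sequence, sequences: Mapping[str, str],
    pvalue: float = DEFAULT_MATCH_P,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Boolean (motif x peak) match matrix, scanning both strands."""
    encoded = {pid: _encode(s) for pid, s in sequences.items()}
    rows = {}
    for motif in pwms:
        qmat = quantized_logodds(motif, background)
        thr = match_threshold(qmat, pvalue, background)
        rc = _revcomp_qmat(qmat)
        rows[motif.matrix_id] = {
            pid: _scan_one(qmat, idx, thr) or _scan_one(rc, idx, thr)
            for pid, idx in encoded.items()
        }
    return pd.DataFrame(rows).T.reindex(columns=list(sequences))


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def tf_gene_for_motif(motif) -> str:
    """Gene symbol for a motif; heterodimer names use the first-named gene."""
    name = getattr(motif, "name", "") or ""
    return name.split("::")[0]


def filter_motifs_by_expression(
    pwms: Sequence, expression_tpm: pd.DataFrame,
    min_tpm: float = 1.0, leukemia_samples: Sequence[str] | None = None,
    motif_to_gene: Mapping[str, str] | None = None,
) -> list:
    """Keep motifs whose TF gene reaches >= min_tpm in >= 1 leukemia sample.

    Motifs whose gene is absent from the expression table (e.g. composite
    dimer names) are kept with a warning.
    """
    cols = list(leukemia_samples) if leukemia_samples is not None else list(
        expression_tpm.columns
    )
    kept = []
    for motif in pwms:
        gene = (motif_to_gene or {}).get(motif.matrix_id) or tf_gene_for_motif(motif)
        if gene not in expression_tpm.index:
            warnings.warn(f"motif {motif.matrix_id}: gene {gene} not measured; kept")
            kept.append(motif)
            continue
        if expression_tpm.loc[gene, cols].max() >= min_tpm:
            kept.append(motif)
    return kept


# ---------------------------------------------------------------------------
# deviations
# ---------------------------------------------------------------------------

def deviations(
    counts, matches: pd.DataFrame, peak_gc: pd.Series,
    n_background: int = 50, seed: int | None = None,
) -> pd.DataFrame:
    """Bias-corrected motif accessibility deviation Z-scores (motifs x samples).

    Raw deviation = (observed - expected)/expected where expected assigns
    each sample's total reads to motif peaks in proportion to the
    cohort-wide read fraction of those peaks. Z-scores subtract the mean and
    divide by the sd of ``n_background`` GC- and accessibility-matched
    background peak-set deviations.
    """
    rng = np.random.default_rng(seed)
    X = counts.matrix.to_numpy(dtype=float)
    peak_ids = list(counts.matrix.index)
    samples = list(counts.matrix.columns)
    matches = matches.reindex(columns=peak_ids).fillna(False)
    col_tot = X.sum(axis=0)
    row_tot = X.sum(axis=1)
    frac = row_tot / row_tot.sum()

    # 10 x 10 background bins on GC and mean accessibility
    gc = peak_gc.reindex(peak_ids).to_numpy(dtype=float)
    acc = np.log1p(X.mean(axis=1))
    gc_bin = np.clip(np.digitize(gc, np.quantile(gc, np.linspace(0, 1, 11)[1:-1])), 0, 9)
    acc_bin = np.clip(np.digitize(acc, np.quantile(acc, np.linspace(0, 1, 11)[1:-1])), 0, 9)
    bin_id = gc_bin * 10 + acc_bin
    bin_members: dict[int, np.ndarray] = {
        b: np.where(bin_id == b)[0] for b in np.unique(bin_id)
    }

    def raw_dev(peak_idx: np.ndarray) -> np.ndarray:
        obs = X[peak_idx].sum(axis=0)
        exp = frac[peak_idx].sum() * col_tot
        return (obs - exp) / np.where(exp > 0, exp, 1.0)

    out = np.full((matches.shape[0], len(samples)), np.nan)
    flagged = []
    for mi, motif_id in enumerate(matches.index):
        peak_idx = np.where(matches.iloc[mi].to_numpy())[0]
        if peak_idx.size == 0:
            flagged.append(motif_id)
            continue
        raw = raw_dev(peak_idx)
        bg_devs = np.empty((n_background, len(samples)))
        for b in range(n_background):
            bg_idx = np.array([
                rng.choice(bin_members[bin_id[p]]) for p in peak_idx
            ])
            bg_devs[b] = raw_dev(bg_idx)
        mu = bg_devs.mean(axis=0)
        sd = bg_devs.std(axis=0, ddof=1)
        # degenerate background spread (compositionally flat data) leaves the
        # centered raw deviation unscaled instead of amplifying float dust
        out[mi] = (raw - mu) / np.where(sd > 1e-8, sd, 1.0)
    dev = pd.DataFrame(out, index=matches.index, columns=samples)
    dev.attrs["flagged_no_match"] = flagged
    return dev


def motif_variability(dev: pd.DataFrame) -> pd.Series:
    """Per-motif variability: sd of deviation Z-scores across the cohort."""
    return dev.std(axis=1, ddof=1).rename("variability")


def differential_motif_activity(
    dev: pd.DataFrame, groups: Mapping[str, str],
    group_a: str, group_b: str,
    p_cut: float = 0.01, delta_cut: float = 0.01,
) -> pd.DataFrame:
    """Difference in mean deviation Z (A - B) with two-sided rank-sum p.

    Significant motifs pass p < ``p_cut`` and |delta| > ``delta_cut``.
    """
    a_cols = [s for s in dev.columns if groups.get(s) == group_a]
    b_cols = [s for s in dev.columns if groups.get(s) == group_b]
    rows = []
    for motif_id in dev.index:
        za = dev.loc[motif_id, a_cols].to_numpy(dtype=float)
        zb = dev.loc[motif_id, b_cols].to_numpy(dtype=float)
        if np.isnan(za).all() or np.isnan(zb).all():
            rows.append({"motif": motif_id, "delta": np.nan, "pvalue": np.nan,
                         "significant": False})
            continue
        delta = np.nanmean(za) - np.nanmean(zb)
        stat, p = sps.ranksums(za[~np.isnan(za)], zb[~np.isnan(zb)])
        rows.append({"motif": motif_id, "delta": float(delta), "pvalue": float(p),
                     "significant": bool(p < p_cut and abs(delta) > delta_cut)})
    return pd.DataFrame(rows).set_index("motif")


def tf_expression_correlation(
    dev: pd.DataFrame, expression_tpm: pd.DataFrame,
    motif_to_gene: Mapping[str, str],
    min_samples: int = 8,
) -> pd.DataFrame:
    """Pearson correlation of motif deviations with TF expression (TPM).

    Samples are matched by id; motifs with < ``min_samples`` paired samples
    or an unmeasured gene get NA. Positive r marks a putative activator.
    """
    rows = []
    for motif_id in dev.index:
        gene = motif_to_gene.get(motif_id)
        r = p = np.nan
        if gene is not None and gene in expression_tpm.index:
            shared = dev.columns.intersection(expression_tpm.columns)
            if len(shared) >= min_samples:
                z = dev.loc[motif_id, shared].to_numpy(dtype=float)
                tpm = expression_tpm.loc[gene, shared].to_numpy(dtype=float)
                ok = ~np.isnan(z)
                if ok.sum() >= min_samples and np.std(tpm[ok]) > 0 and np.std(z[ok]) > 0:
                    r, p = sps.pearsonr(z[ok], np.log1p(tpm[ok]))
        rows.append({"motif": motif_id, "gene": gene, "r": r, "pvalue": p,
                     "putative_activator": bool(r > 0) if not np.isnan(r) else False})
    return pd.DataFrame(rows).set_index("motif")


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def footprint_score(
    coverage_profiles: np.ndarray, center_width: int, flank_width: int
) -> float:
    """Center-depletion footprint score over motif-centered signal profiles.

    ``coverage_profiles`` is (sites x width). The score is
    mean(flank signal) - mean(center signal), averaged over sites; higher
    means a stronger footprint. This is a deliberately simplified
    center-vs-flank statistic, not a full bias-corrected footprinter.
    """
    profiles = np.atleast_2d(np.asarray(coverage_profiles, dtype=float))
    width = profiles.shape[1]
    mid = width // 2
    half_c = center_width // 2
    center = profiles[:, mid - half_c: mid - half_c + center_width]
    left = profiles[:, max(0, mid - half_c - flank_width): mid - half_c]
    right = profiles[:, mid - half_c + center_width:
                     mid - half_c + center_width + flank_width]
    flank = np.concatenate([left, right], axis=1)
    return float((flank.mean(axis=1) - center.mean(axis=1)).mean())
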