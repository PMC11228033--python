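"""Core statistics: NB Wald differential test, effect sizes, enrichment, GSEA.

The differential test is a per-feature negative-binomial GLM with a two-group
design and log effective-library-size offsets. Dispersions are estimated by a
per-feature method of moments with a floor (optional trended shrinkage); the
group means are fitted by Newton iterations on the log scale, vectorized
across features. Wald z = log2FC / SE with a standard-normal reference,
BH-adjusted across tested features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DIFF_COLUMNS = ["baseMean", "log2FC", "SE", "stat", "pvalue", "FDR", "status"]

LN2 = math.log(2.0)
MAX_NEGLOG10_FDR = 320.0
DISPERSION_FLOOR = 1e-8


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# negative-binomial Wald test
# ---------------------------------------------------------------------------

def _fit_group_logmean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                       n_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature NB MLE of the log group mean with offsets.

    y: features x samples counts, s: per-sample effective sizes,
    alpha: per-feature dispersion. Returns (log-mean b, Fisher information).
    """
    q = y / s[None, :]
    mean_q = q.mean(axis=1)
    # half-count pseudo start for all-zero groups so the Wald stat stays finite
    b = np.log(np.where(mean_q > 0, mean_q, 0.5 / s.mean()))
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(b)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = s[None, :] * np.exp(b)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return b, info


def estimate_dispersion(y: np.ndarray, s: np.ndarray, groups_idx: Sequence[np.ndarray],
                        floor: float = DISPERSION_FLOOR,
                        trended: bool = False) -> np.ndarray:
    """Method-of-moments NB dispersion from within-group residual variance."""
    q = y / s[None, :]
    n_total = sum(len(ix) for ix in groups_idx)
    resid_ss = np.zeros(y.shape[0])
    for ix in groups_idx:
        gm = q[:, ix].mean(axis=1, keepdims=True)
        resid_ss += ((q[:, ix] - gm) ** 2).sum(axis=1)
    df = max(n_total - len(groups_idx), 1)
    var_w = resid_ss / df
    mu_bar = q.mean(axis=1)
    inv_s = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mu_bar * inv_s) / np.where(mu_bar > 0, mu_bar ** 2, 1.0)
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.maximum(alpha, floor)
    if trended:
        # shrink toward the median dispersion of features with similar mean
        order = np.argsort(mu_bar)
        trend = np.empty_like(alpha)
        n_bins = max(min(20, len(alpha) // 50), 1)
        bins = np.array_split(order, n_bins)
        for binned in bins:
            trend[binned] = np.median(alpha[binned])
        alpha = np.sqrt(alpha * np.maximum(trend, floor))
    return alpha


def nb_wald(counts, contrast: tuple[str, str], factors=None,
            trended_dispersion: bool = False) -> pd.DataFrame:
    """Two-group NB Wald differential test (group2 vs group1 log2 fold change).

    ``counts`` is a :class:`cimpomics.quantify.CountMatrix`; ``factors`` an
    optional :class:`cimpomics.quantify.NormalizationFactors` (defaults to
    TMM-free library-size-only offsets). Returns a DataFrame with columns
    ``baseMean, log2FC, SE, stat, pvalue, FDR, status`` indexed by feature.
    """
    g1, g2 = contrast
    sample_groups = counts.groups
    s1 = [s for s in counts.matrix.columns if sample_groups.get(s) == g1]
    s2 = [s for s in counts.matrix.columns if sample_groups.get(s) == g2]
    for name, ss in ((g1, s1), (g2, s2)):
        if name not in set(sample_groups.values()):
            raise ValueError(f"unknown group label: {name}")
        if len(ss) < 2:
            raise ValueError(f"group {name} has fewer than 2 samples")

    samples = s1 + s2
    y = counts.matrix[samples].to_numpy(dtype=float)
    libsize = y.sum(axis=0)
    if factors is not None:
        f = np.array([factors.factors[s] for s in samples])
    else:
        f = np.ones(len(samples))
    s_eff = f * libsize
    s_eff = s_eff / np.exp(np.mean(np.log(s_eff)))  # geometric-mean anchored

    idx1 = np.arange(len(s1))
    idx2 = np.arange(len(s1), len(samples))
    nonzero = y.sum(axis=1) > 0

    n_feat = y.shape[0]
    log2fc = np.full(n_feat, np.nan)
    se = np.full(n_feat, np.nan)
    stat = np.full(n_feat, np.nan)
    pval = np.full(n_feat, np.nan)
    base_mean = (y / s_eff[None, :]).mean(axis=1)
    status = np.where(nonzero, "ok", "all-zero")

    if nonzero.any():
        yz = y[nonzero]
        alpha = estimate_dispersion(yz, s_eff, [idx1, idx2], trended=trended_dispersion)
        b1, i1 = _fit_group_logmean(yz[:, idx1], s_eff[idx1], alpha)
        b2, i2 = _fit_group_logmean(yz[:, idx2], s_eff[idx2], alpha)
        lfc = (b2 - b1) / LN2
        se_z = np.sqrt(1.0 / np.maximum(i1, 1e-12) + 1.0 / np.maximum(i2, 1e-12)) / LN2
        z = lfc / se_z
        # t reference with residual df: the dispersion is estimated from few
        # samples, so a normal reference is anti-conservative at this n
        df_resid = max(len(idx1) + len(idx2) - 2, 1)
        p = 2.0 * sps.t.sf(np.abs(z), df=df_resid)
        log2fc[nonzero] = lfc
        se[nonzero] = se_z
        stat[nonzero] = z
        pval[nonzero] = p
        zero_grp = (yz[:, idx1].sum(axis=1) == 0) | (yz[:, idx2].sum(axis=1) == 0)
        st = status[nonzero]
        st[zero_grp] = "zero-group"
        status[nonzero] = st

    fdr = bh_adjust(pval)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "SE": se,
            "stat": stat,
            "pvalue": pval,
            "FDR": fdr,
            "status": status,
        },
        index=counts.matrix.index,
    )


# ---------------------------------------------------------------------------
# Welch's t and Cohen's d
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeSummary:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    cohen_d: float
    welch_t: float
    welch_p: float
    size_label: str
    flagged: bool = False


def welch_cohen(group1: Sequence[float], group2: Sequence[float]) -> EffectSizeSummary:
    """Welch's unequal-variance t-test with Cohen's d.

    d = (mean1 - mean2) / sqrt((sd1^2 + sd2^2) / 2); |d| < 0.2 is labeled
    small, >= 0.8 large, otherwise medium.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 values")
    m1, m2 = x1.mean(), x2.mean()
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    pooled = math.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0:
        d = float("nan")
        flagged = True
        label = "undefined"
    else:
        d = (m1 - m2) / pooled
        flagged = False
        label = "small" if abs(d) < 0.2 else ("large" if abs(d) >= 0.8 else "medium")
    t, p = sps.ttest_ind(x1, x2, equal_var=False)
    return EffectSizeSummary(m1, m2, s1, s2, d, float(t), float(p), label, flagged)


# ---------------------------------------------------------------------------
# region-set enrichment (one-sided Fisher)
# ---------------------------------------------------------------------------

def fisher_region_enrichment(query, universe, database: Mapping[str, Sequence]) -> pd.DataFrame:
    """One-sided (greater) Fisher enrichment of interval sets in a query.

    Membership is >= 1 bp overlap; the query is intersected with the universe
    first. Odds ratios use the sample (ad/bc) convention, with infinite odds
    flagged rather than corrected.
    """
    from .features import build_tree, tree_overlaps

    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    universe_keys = {key(iv) for iv in universe}
    query_keys = {key(iv) for iv in query} & universe_keys

    rows = []
    for set_name, ivs in database.items():
        trees = build_tree(ivs)
        in_set = {key(iv) for iv in universe if tree_overlaps(trees, iv)}
        a = len(query_keys & in_set)
        b = len(query_keys) - a
        c = len(in_set - query_keys)
        d = len(universe_keys) - a - b - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        if b * c > 0:
            odds = (a * d) / (b * c)
            flagged = False
        else:
            odds = math.inf if a * d > 0 else math.nan
            flagged = True
        rows.append({"set": set_name, "odds_ratio": odds, "pvalue": p,
                     "a": a, "b": b, "c": c, "d": d, "flagged": flagged})
    df = pd.DataFrame(rows).set_index("set")
    df["FDR"] = bh_adjust(df["pvalue"].to_numpy())
    return df.sort_values(["pvalue", "odds_ratio"], ascending=[True, False])


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def rank_metric(diff: pd.DataFrame, max_score: float = MAX_NEGLOG10_FDR) -> pd.Series:
    """Ranking metric -log10(FDR) x sign(log2FC), NA features excluded.

    FDR underflow is capped at ``max_score``; ties order deterministically by
    feature id in the downstream ranking.
    """
    ok = diff["FDR"].notna() & diff["log2FC"].notna()
    sub = diff.loc[ok]
    with np.errstate(divide="ignore"):
        score = -np.log10(sub["FDR"].to_numpy())
    score = np.minimum(score, max_score)
    metric = score * np.sign(sub["log2FC"].to_numpy())
    out = pd.Series(metric, index=sub.index, name="rank_metric")
    return out.iloc[np.lexsort((out.index.astype(str), -out.to_numpy()))]


def _es_from_positions(weights_sorted: np.ndarray, total_n: int,
                       positions: np.ndarray) -> tuple[float, int]:
    """Enrichment score from sorted 0-based hit positions.

    ``weights_sorted`` holds |metric|^weight for the full ranked list.
    Returns (ES, peak position index in the ranked list).
    """
    pos = np.sort(positions)
    k = len(pos)
    hit_w = weights_sorted[pos]
    total_w = hit_w.sum()
    if total_w == 0:  # degenerate: uniform hit increments
        hit_w = np.ones(k)
        total_w = float(k)
    miss_unit = 1.0 / (total_n - k)
    cum_hit = np.cumsum(hit_w) / total_w
    # running sum just after each hit, and just before each hit
    after = cum_hit - (pos + 1 - np.arange(1, k + 1)) * miss_unit
    before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - np.arange(k)) * miss_unit
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), int(pos[i_max])
    return float(before[i_min]), int(pos[i_min])


def preranked_gsea(ranked: pd.Series, gene_sets: Mapping[str, Sequence[str]],
                   min_size: int = 15, max_size: int = 5000,
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int | None = None) -> pd.DataFrame:
    """Classic weighted running-sum GSEA with gene-label permutation p-values.

    ``ranked`` is the metric indexed by gene id, already sorted (see
    :func:`rank_metric`). NES scales ES by the mean |permutation ES| of the
    same sign; FDR is BH across reported sets.
    """
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    weights_sorted = np.abs(ranked.to_numpy()) ** weight

    rows = []
    for set_name, members in gene_sets.items():
        pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        k = len(pos)
        if not (min_size <= k <= max_size):
            continue
        es, peak = _es_from_positions(weights_sorted, n, pos)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            perm_pos = rng.choice(n, size=k, replace=False)
            perm_es[i], _ = _es_from_positions(weights_sorted, n, perm_pos)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        denom = np.abs(perm_es[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        if es >= 0:
            leading = [genes[p_] for p_ in pos if p_ <= peak]
        else:
            leading = [genes[p_] for p_ in pos if p_ >= peak]
        rows.append({"set": set_name, "size": k, "ES": es, "NES": nes,
                     "pvalue": p, "leading_edge": ",".join(map(str, leading))})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.set_index("set")
    df["FDR"] = bh_adjust(df["pvalue"].to_numpy())
    return df.sort_values("pvalue")
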