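# Methods

This note documents the models, parameter choices and numerical decisions
behind `cimpomics`, and what the synthetic cohort does and does not emulate.

## Differential count model

Counts for every assay (methylation enrichment, ATAC, H3K27ac, CTCF,
expression, Hi-C scores) are modeled per feature as negative binomial with
a two-group log-linear mean and per-sample offsets:

    y_ij ~ NB(mu_ij, alpha_i),    log mu_ij = log s_j + b_{g(j)}

where s_j is the effective library size (TMM factor × total counts,
geometric-mean anchored) and b_g the group log-mean. Dispersions alpha_i
are estimated by a per-feature method of moments — within-group residual
variance of offset-normalized counts, alpha = (var − mean/s̄)/mean²,
floored at 1e-8 — with an optional trended-shrinkage toggle (geometric
interpolation toward the binned median, off by default). Group means are
fitted by damped Newton iterations on b (score and Fisher information in
closed form), vectorized across features; 30 iterations with steps clipped
to ±5 are far past convergence for these data. The Wald statistic is
log₂FC/SE with SE from the inverse Fisher information of both groups.

Because the dispersion is itself estimated from n₁+n₂ samples, p-values use
a t reference with n₁+n₂−2 degrees of freedom rather than a standard
normal; at the cohort sizes used here a normal reference is measurably
anti-conservative (empirical type-I ≈ 0.065–0.07 at nominal 0.05) whereas
the t reference sits at ≈ 0.05–0.06. This deliberately simplifies the
empirical-Bayes dispersion machinery of DESeq2-family tools; a test
cross-checks that fold-change estimates track pyDESeq2's on shared data.
Features that are all-zero across samples are flagged `all-zero` and
reported as NA, never dropped; a group that is all-zero gets a half-count
pseudo-start so the statistic stays finite and is flagged `zero-group`.

TMM normalization follows the published method exactly: pairwise M and A
values against a reference sample (75th-percentile rule), features zero in
either sample excluded, 30% of extreme M and 5% of extreme A trimmed from
each tail by rank, precision-weighted mean of remaining M, and factors
rescaled to geometric mean 1. Input-DNA subtraction (when input counts are
supplied) floors at zero and precedes factor computation.

## Feature catalogs

The CpG-island detector slides a 200 bp window at 1 bp steps, requires
GC > 0.5 and observed/expected CpG > 0.6 with expected = (#C·#G)/length,
merges overlapping qualifying windows, and re-tests each merged region
against the same thresholds. N bases never count toward GC or CpG; window
length stays the denominator. The same definition, written as naive loops,
serves as the exhaustive oracle in the tests.

"Overlapping a TSS window by at least 5% of the peak's width" is computed
against the *union* of TSS windows and is inclusive at 5%. Peak-to-sample
support and master-list membership use ≥ 1 bp overlap; per-sample peaks
need −log₁₀(q) strictly above 10 to count as support, and supported peaks
from ≥ 2 samples merge into maximal unions (blacklist removal happens
after significance filtering, before merging).

## Integrations

Starburst axes are signed −log₁₀(FDR) scores (FDR floored at 1e-320 before
the log); the correlation summary reports Pearson r both on these scores
and on raw log₂ fold changes, since either convention appears in practice.
Enhancer–gene assignment is an ensemble: candidates are genes within 1 Mb
and in the same TAD (distance-only with a flag when the enhancer lies
outside all TADs); evidence flags are loop contact (padded anchors touch
both elements), database assignment, enhancer–promoter accessibility
correlation (Pearson on log1p counts, ≥ 0.3 over ≥ 8 shared samples), and
nearest gene. The winner has the most flags; ties break by
loop > database > correlation > nearest, then smallest distance — a total
order, so assignment is deterministic. The 1 Mb and r ≥ 0.3 defaults are
generator-calibrated conveniences, not biological constants.

## Motif activity

PWM log-odds (pseudocount-regularized probabilities over a uniform
background) are quantized to 1e-3 bits so the match threshold can be taken
from the *exact* dynamic-programming score distribution under the
background; the threshold is the smallest achievable score with upper-tail
probability ≤ 5×10⁻⁵, and an exhaustive k-mer enumeration reproduces it
exactly for short motifs. Scanning covers both strands.

Deviations follow the chromVAR construction: a sample's expected reads in
a motif's peaks equal the cohort-wide read fraction of those peaks times
the sample total; the raw deviation (obs − exp)/exp is Z-scored against 50
background peak sets matched on GC and mean accessibility in a 10 × 10
quantile grid, sampled with replacement (a simplification of the cited
method's Mahalanobis sampling). The Z-scores are therefore invariant to
depth only up to the pooled-fraction weighting and background noise; a
degenerate background spread (compositionally flat data) leaves the
centered raw deviation unscaled rather than dividing by float dust.
Differential activity is the difference in mean Z with a two-sided
rank-sum test, significant at p < 0.01 and |Δ| > 0.01. The footprint score
is deliberately a simplified center-vs-flank depletion statistic, labeled
as such — not a bias-corrected footprinter. Heterodimer motif names map to
the first-named gene for the TPM filter and expression correlation.

## CTCF coupling and 3D genome

CpG motif positions are 1-based positions of the CpG's C in motif-forward
orientation (reverse-strand sites must arrive reverse-complemented); the
canonical CTCF motif used by the generator is 19 bp with CpGs plantable at
positions 5 and 15 and a CpG-free backbone elsewhere, mirroring the
CpG-poor canonical motif. The methylation join keeps one CTCF peak per
region by maximal overlap, ties by smallest FDR then id. Binding classes
use FDR < 0.05 and |log₂FC| > 1; class-wise methylation comparisons are
reported without multiplicity adjustment, as is conventional for these
box-plot summaries.

TAD boundaries are 5 kb regions centered on borders (the TAD-calling
resolution); each keeps at most the smallest-FDR overlapping CTCF peak,
ties by genomic start. Loop anchors are padded by 5 kb per side; EP loops
need an enhancer and a promoter within 25 kb (inclusive, interval gap with
0 for overlap) of *opposite* padded anchors. "Decreased CTCF binding" in
the loop linkage defaults to sign-only (log₂FC < 0 at any anchor peak)
with a significance-gated variant reported alongside, since either reading
is defensible. Integer Hi-C score tables run through the NB Wald test;
non-integer scores fall back to a Welch test on log₂(score+1), with the
mode recorded.

## Variant sieve

Caller tables merge on parsimony-trimmed (prefix then suffix, one base
kept) coordinates, which unifies the redundant indel representations
callers emit; full reference-based left-alignment is out of scope and the
trimming convention is documented here instead. The strand-bias statistic
is the alt-forward fraction and must lie strictly inside (0,1) within the
padded exome capture. The quality rules run in a fixed order and every
variant records a complete ordered trail; a missing required metric fails
the variant with reason `metric-missing` rather than passing silently. SNV
clusters (≥ 3 passing SNVs with consecutive gaps < 5 bp) are removed after
the per-site rules, wholesale. Somatic selection applies the region,
consequence, VAF, population-frequency (with COSMIC-hematological and
clonal-hematopoiesis-gene rescues), donor and blacklist rules
conjunctively; annotation fields arrive as input columns — the sieve never
queries external databases. Splice-acceptor membership is an input flag
(operationally ±2 bp of exon boundaries upstream of the sieve).

## Pre-ranked GSEA

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum (weight exponent 1 by default, exposed); ties in the ranking metric
break by feature id. P-values come from plain gene-label permutation —
sets of the same size resampled from the ranked universe — with the +1
convention, sign-matched; NES divides by the mean |permutation ES| of the
same sign. This approximates the multilevel split Monte-Carlo p-values of
fgsea; for the property checks used here (exact ES, null uniformity) the
plain scheme suffices. The FDR-underflow cap for the ranking metric is
320.

## The synthetic cohort

Group sizes default to CIMP 9, AML 20, T-ALL 15, HSPC 3 — the epigenomics
cohort scale this class of study works at. Counts are negative binomial
(gamma–Poisson) with a single configurable dispersion (default 0.1, a
typical between-patient value for bulk assays); library scales are
log-uniform and rescaled to span exactly [1, 3]× so TMM is never trivial.
Methylation is represented as MCIP-like enrichment counts over regions,
not array beta values. Planted structure:

* `effect_log2fc` (default −3) silences a fraction
  (`frac_silenced_tfs`, default 0.3) of CpG-island TF genes in CIMP:
  promoter methylation ×2^|e|, expression ÷2^|e|, enhancer and promoter
  accessibility ÷2^(|e|/2). It also gates the motif-activity layer (a
  doubling of planted-motif peaks tracking a CIMP-high activity latent
  also driving one TF's expression), differential loops/TADs, and EP-loop
  → expression coupling (gene log₂FC = 0.8 × loop log₂FC).
* `meth_expr_rho` (default −0.3) drives a continuous layer whose true
  promoter-methylation and expression log₂ fold changes are exactly
  ρ-correlated (bivariate normal latents, σ = 1.5 on the log₂ scale);
  ρ = 0 disables the layer entirely so the all-effects-off configuration
  is exchangeable across groups.
* `ctcf_coupling_beta` (default 4) scales CTCF binding means by
  2·sigmoid(−β·m) — normalized so β = 0 or methylation m = 0 is exactly
  neutral — only at sites with a CpG at motif position 5 or 15.
  Hypermethylation in CIMP (m ≈ 0.8 vs baseline ≈ 0.1) is planted at 50%
  of CpG-flagged and 20% of unflagged sites when β > 0; flagged
  hypermethylated sites form the lost set. Methylation enrichment at CTCF
  sites follows 2^(3·Δm), and MCIP covers 60% of sites (the real assay
  covers a CpG-rich minority).
* `loop_ctcf_coupling` (default 0.7): every lost loop (30% of CTCF–CTCF
  loops at ¼ density, plus EP loops whose planted delta < −1) receives,
  with this probability, an anchor CTCF site from the lost set —
  CTCF–CTCF loops by re-anchoring, EP loops by relocating an otherwise
  unused lost site into the enhancer anchor. Gained loops anchor at
  unchanged sites.

What the generator does *not* emulate: read-level data (no FASTQ/BAM, no
peak calling), raw Hi-C contact matrices, array data, linkage
disequilibrium or mutational signatures in the variant tables, batch
effects, GC-dependent coverage bias, and the correlated mean–dispersion
trends of real libraries. Passing the recovery tests therefore shows that
each stage's logic is correct and calibrated under its stated model — not
that the model captures every property of patient data.

## Problem sizes and tolerances

The test suite and acceptance script size their simulations to what the
checks need: 5000 null features at 10 vs 10 samples for type-I
calibration (empirical rate required in [0.03, 0.07], KS uniformity
p > 0.01), ≥ 200 planted silenced TFs for fold-change recovery (median
within ±0.3 of −3), 2000 genes for correlation recovery (±0.1 of the
planted −0.3; null |r| < 0.05), 20 seeded replicates for the rate-style
checks (motif gates, CpG positions 5/15, lost-vs-gained loop direction,
each requiring ≥ 95% success), and exact oracle agreement for CGI
detection (interval equality), TMM (1e-10), motif thresholds (integer
equality) and GSEA running sums (1e-12). The default cohort is ~1000
regions per assay over a 20 Mb two-chromosome toy genome; smaller
configurations used in unit tests keep the same structure.

## Known limitations

* The NB dispersion estimator is method-of-moments; at very low counts or
  n < 4 per group the Wald test loses calibration faster than an
  empirical-Bayes estimator would.
* The motif background model is i.i.d. uniform (configurable base
  frequencies, no Markov background).
* GSEA p-values are plain-permutation, so their resolution is 1/(n_perm+1).
* The enhancer-assignment precedence is a pragmatic total order, not a
  learned weighting; on real data its accuracy depends on the quality of
  the loop and database layers.
* Interval joins are exact and half-open throughout; 1-based inputs must
  be converted at the boundary by the caller.
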