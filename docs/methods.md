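# Methods

`spikecal` implements the quantitative core of spike-in calibrated
sequencing experiments (calibrated nuclear RNA-seq, ATAC-seq and ChIP-seq):
a fixed quantity of cells from a second species is mixed into every sample,
so reads mapping to the exogenous genome provide a condition-invariant
yardstick for between-sample normalization. This note records the model,
the defaults, and the numerical choices, in the package's own words.

## Dual-genome accounting and calibration factors

Every gene carries a genome tag (`target` or `spike`); every assay sample
has a matched input-gDNA sample sequenced from the same cell mixture.

**Input mixing ratio.** r_s = (spike read total) / (target read total) in
the matched input. Because input gDNA has no assay enrichment, r_s measures
the realized spike:target cell-mixing proportion of sample s. A zero target
total is an error; a zero spike total yields an unusable ratio (0, with a
warning).

**Track-scale (subsampling) factors.** The input-corrected spike depth is
a_s = (assay spike total)_s / r_s; dividing by r_s cancels sample-to-sample
variation in how much spike material was actually mixed in, leaving a_s
proportional to the effective sequencing depth of the shared biological
material. Factors are referenced to the minimum: f_s = min(a) / a_s, so
every factor lies in (0, 1], the lowest-depth sample keeps all of its reads,
and no library is ever up-sampled. The reference choice (minimum-depth
sample rather than a designated control) is configurable in principle but
the minimum convention is the default because it is the only one that
guarantees factors ≤ 1.

**Spike-anchored size factors.** For differential testing, each sample's
spike-gene counts are first divided by r_s / median(r) (the median-centring
keeps factors near 1 and comparable across runs), then median-of-ratios
size factors are computed over spike genes only: the reference is the
per-gene geometric mean across samples, genes with a zero count in any
sample are excluded from the reference (the standard convention), and
σ_s is the median ratio of sample s's pre-normalized counts to the
reference. If fewer than two spike genes survive the zero filter the
computation fails loudly rather than degrade silently. These σ_s normalize
the *target*-gene counts in the differential test — that indirection is the
entire point: a genuinely global shift in the target transcriptome leaves
the spike-in untouched, so spike-anchored factors preserve it, whereas
total-count factors absorb it.

**Subsampling.** Track subsampling is binomial thinning (each read kept
independently with probability f_s), chosen over exact hypergeometric
sampling for streamability; it is seeded and reproducible. Equal-depth
downsampling of histone ChIP libraries (which carry no spike-in) is exact
and without replacement — every library is reduced to the minimum total —
because a common exact total is the contract of that operation.

## Differential test

A deliberately transparent two-condition negative-binomial pipeline with
externally supplied size factors; mean μ, variance μ + αμ².

* **Dispersion**: per-gene method of moments on normalized counts with
  variances pooled *within* condition (so a real condition effect does not
  inflate α̂): α̂ = max(floor, (v − m)/m²), floor 1e-8 to keep the
  likelihood defined at zero estimated overdispersion. No shrinkage across
  genes, no trend fitting, no LFC moderation, no independent filtering —
  the calibration logic needs only a consistent NB test, and all package
  guarantees are checked against simulation truth.
* **Fit**: per condition, the gene's log-mean β solves the NB score
  equation Σ_i (y_i − μ_i)/(1 + α μ_i) = 0 with μ_i = σ_i e^β (size
  factors enter as offsets), by vectorized Fisher scoring across all genes
  simultaneously. log2FC is the condition contrast in log2 units; its
  standard error comes from the Fisher information Σ μ/(1 + αμ).
* **Reference distribution**: with a handful of replicates the plug-in
  dispersion makes the usual normal reference anti-conservative
  (empirically ≈0.10 at nominal 0.05 with four replicates per group), so
  the Wald statistic is compared against t with n1 + n2 − 2 degrees of
  freedom, which restores the nominal level; `wald_reference="normal"`
  gives the plain asymptotic test. At large replication the two coincide.
* **Degenerate genes**: all-zero genes get NA statistics and are never
  called. A gene with zero counts in exactly one condition has no finite
  MLE; a 0.5 continuity adjustment on that group's total keeps log2FC and
  SE finite (flagged in the output).
* **Multiple testing**: Benjamini–Hochberg step-up (via statsmodels), NAs
  ignored and propagated.
* **Calls**: `up` iff adjusted p < 0.05 and 2^log2FC > 1.4, `down`
  symmetric, else `ns`. Both thresholds are strict inequalities and the
  fold threshold applies to the unshrunk estimate (the package computes no
  shrunk estimate).

A note on invariances: scaling *all* samples' counts and size factors
jointly by c leaves every log2FC exactly unchanged (p-values legitimately
change — c times the counts is c times the information). Rescaling a
*single* sample's counts and size factor jointly is only approximately
neutral for any GLM with offsets, because the rescaled sample carries the
weight of a deeper library; the tests check the exact global form and the
within-noise single-sample form.

## Signal quantitation

Coordinates are 0-based half-open throughout; the TSS of a minus-strand
gene is its interval end − 1. Coverage tracks store per-bin signal totals
with signal uniform within a bin, so the cumulative curve is piecewise
linear and any sub-bin interval receives a length-proportional share. That
fractional-overlap rule is what makes the conservation property exact: the
row sum of a TSS matrix equals the interval count over the same window.

* `tss_matrix`: fixed-width windows centred on the TSS, minus-strand rows
  reversed so transcription always runs left to right; off-contig bins are
  NaN.
* `scaled_body_matrix`: gene bodies resampled to a fixed bin count by
  length-weighted averaging; rows are densities (signal per bp) so genes of
  different lengths with the same relative shape give identical rows.
  Genes shorter than the bin count are excluded and counted.
* `ratio_track`: per-bin (num + pc)/(den + pc) with pseudocount default
  1 signal unit, bounding ratios at empty bins (used for e.g. H3K36me2
  over H3 to control for nucleosome density).
* Blacklist filtering removes any record overlapping a blacklist interval
  by ≥ 1 bp under half-open semantics (abutting records are kept).
* Replicate correlation reports pairwise Pearson r and a merge gate
  (all pairwise r above 0.95 by default).
* Expression quartiles are rank-based with stable input-order tie-breaks,
  so quartile sizes differ by at most one even for constant input.

Window defaults that the quantitation exposes (promoter window TSS ± 500 bp
for promoter counting, metaprofile flank and bin sizes) are parameters with
documented defaults, not fixed constants.

## RNAPII pausing

Pausing index = promoter-window signal density / gene-body signal density,
strand-aware. Defaults follow the common convention: promoter TSS−30 to
TSS+300, body TSS+300 to the TES; genes shorter than 1 kb are excluded so
the windows cannot overlap, and a zero body density yields an invalid
record rather than an infinite index. The ECDF summary is computed over
valid records only (invalid counts are reported) and supports side-by-side
condition comparison. Phospho-isoform changes are per-interval double
ratios (Ser/NTD in treated over Ser/NTD in untreated), invalid when the
total-RNAPII (NTD) denominator is empty.

## Gene classification

A gene is CGI-associated when its promoter window (TSS ± 1 kb by default)
overlaps a CpG-island interval. Among CGI-associated genes, promoters
overlapping BOTH a RING1B and a SUZ12 interval are polycomb-occupied
(PRC); the rest are non-PRC; all remaining genes are non-CGI regardless of
polycomb overlap. The three classes always partition the gene set, and
enlarging the promoter window can only add CGI associations, never remove
them. Overlap is evaluated at the promoter window (not gene-wide).

## Synthetic data generator

The generator emulates the structure of a two-condition (UNT/OHT)
spike-in calibrated experiment with 3–4 replicates per condition:

* **Mixing**: the nominal spike cell fraction defaults to 0.25
  (2.5 × 10⁶ spike cells into 1 × 10⁷ target cells); the realized
  per-sample ratio is log-normal around it with CV `mixing_cv`
  (default 0.05 — the per-replicate variability is not known from any
  published value, so it is an exposed parameter).
* **Counts**: NB(μ, μ + αμ²), α = 0 degenerating to Poisson. Target gene
  means are baseline × 2^(log2FC·[treated]) × sample-depth factor;
  spike gene means scale with the realized mixing ratio and the depth
  factor but never with condition — the premise of the method encoded as
  ground truth. Baselines are log-normal (log-sd 1.5) with a configurable
  20% of genes forced lowly expressed (×0.05), reflecting that
  low-expression genes are where calibration matters most.
* **Depth**: `mean_depth` is the expected target read total of an
  *untreated* sample; treated totals exceed it when genes are shifted up,
  which is exactly the situation total-count normalization cannot detect.
  Per-sample depth factors are log-normal with CV 0.1.
* **Inputs**: matched input-gDNA samples share the assay sample's realized
  mixing ratio and have uniform per-gene means within each genome (no
  assay enrichment), so their spike/target total estimates the mixing
  ratio; they use the same NB dispersion as the assay counts for
  simplicity.
* **Tracks**: toy contigs with non-overlapping alternating-strand genes,
  each with a promoter peak and body plateau of known density (defaults
  10 and 2 signal units/bp), so expected pausing indices and metaprofiles
  are exact by construction; treated samples multiply the body density of
  shifted genes by 2^shift_log2fc. CGI flags on even-indexed genes and
  polycomb flags on every fourth give classification an exact expected
  answer.
* **Determinism**: one seed governs everything through spawned
  substreams; identical seeds give bit-identical matrices, tracks and
  pipeline artifacts.

What the generator does *not* emulate: GC/length biases, PCR duplicates,
mappability, peak structure beyond the two-level promoter/body shape,
batch effects, or any correlation structure between genes. Passing tests
therefore certify the calibration arithmetic, the estimator's statistical
calibration, and the geometry of the quantitation — not robustness to the
full messiness of real libraries.

## Problem sizes and runtime

The acceptance-scale simulation uses 20,000 target + 2,000 spike genes at
2 × 10⁶ target reads per sample with 3 replicates per condition — the
scale of the real design — and completes in seconds because the NB fits
are vectorized across genes. At that per-gene depth (~100 reads) with
three replicates and the strict published call rule, median fold-change
recovery is excellent while individual-gene significance is power-limited;
the reported recovery fractions reflect that honestly. Unit tests use
hundreds of genes; the shipped demo config runs end to end in seconds.

## Known limitations

* Two-condition designs only; no covariates, no multi-factor models.
* No dispersion/LFC shrinkage; per-gene estimates are noisy at very low
  replication (the t reference compensates for the test level, not for
  estimator variance).
* Mixing ratios must come from matched inputs; there is no fallback
  estimator from assay alignment statistics.
* bedGraph is the only track format in core (text, auditable); bigwig is
  out of scope.
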