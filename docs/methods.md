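# Methods

This note documents the models, defaults and numerical choices behind
`mchscape`, and what the synthetic-data generator does and does not emulate.

## Methylation detection

**Integration.** For cytosine $i$ with per-aligner total reads $t_{ij}$ and
unconverted reads $M_{ij}$, the integrated level is the read-depth weighted
average $\sum_j M_{ij} / \sum_j t_{ij}$ minus the bisulfite non-conversion
rate, clamped at 0. The non-conversion rate is a required per-sample input
(typically ~0.5%; a warning is raised above 5%); a convenience estimator
returns the pooled raw $M/t$ over a designated fully-unmethylated control
contig (a lambda-spike-in analogue, present in synthetic datasets as
`chrCtrl`). Sites missing from an aligner contribute $t = 0$; integration is
therefore invariant to relabelling aligners or splitting one aligner's
counts into pseudo-aligners.

**Coverage filter.** Defaults keep sites with pooled depth ≥ 5 covered by
≥ 2 aligners. The stricter literal reading (≥ 6 reads, all 3 aligners) is
selectable via `min_depth` / `min_aligners`.

**Calling.** The test statistic is the upper-tail binomial probability
$\Pr(X \ge k_i)$ with success probability equal to the non-conversion rate.
The upper tail (including $k_i$) is the standard conservative reading of
"probability that $k_i$ methylated reads occur out of $n_i$"; a point
probability would not order sites by evidence. Calls use strict inequality
(p-value < threshold, default $10^{-5}$) on the raw pooled counts, not on
the subtracted level.

**FDR calibration.** An artificial methylome preserves every site's depth
and draws null methylated counts $k^\* \sim \mathrm{Bin}(n_i, p)$.
$\mathrm{FDR}(t)$ = null calls / real calls over a descending threshold
grid ($10^{-2} \ldots 10^{-8}$ by default); the chosen threshold is the
largest $t$ with $\mathrm{FDR}(t)$ below the 0.01 target, or absent when
none achieves it (the curve is always returned; FDR is NaN where there are
no real calls). One artificial replicate per seed by default,
`n_replicates` averages several. With the seed fixed the procedure is
bit-reproducible.

**Status cutoffs used downstream.** mCpG: level ≥ 0.8; unmethylated CpG:
level < 0.2; hyper-methylated CpH: level > 0.5. The mCpH status used for the
distance *probability* profile is the binomial call, not the 0.5 cutoff
(the level cutoff would miss the bulk of low-level CpH methylation).

## Landscape analysis

The genome is cut into 1-kb blocks carrying unweighted per-class and
per-strand mean levels. The block mCpG–mCpH Pearson correlation uses blocks
with more than 10 CpGs and more than 10 CpHs (NaN if a vector is constant;
an error below 3 qualifying blocks). An optional genic annotation labels
blocks promoter (TSS ± 5 kb) / intragenic (TSS..TTS) / intergenic when more
than 500 bp of the block is covered, promoter taking precedence.

Hemi-methylation: blocks with |mean mCpG(+) − mean mCpG(−)| > 0.5 contribute
a (cis, trans) pair — mean mCpH on the higher-mCpG strand vs the other — and
the paired difference is tested with the Wilcoxon signed-rank test.

Distance profiles orient offsets 5'→3' on the anchor CpG's strand
(negative = upstream of the anchor cytosine); a strand-agnostic convention
would cancel the asymmetric −4 bp peak. The probability profile counts, per
10-bp offset block within ±500 bp, the fraction of anchor windows whose
block contains ≥ 1 called mCpH (the "more than one" reading, > 1, is
exposed via `min_mcph_per_block`), with anchors split by CpG status (≥ 0.8
vs < 0.2) and mCpHs taken from both strands. The level profile is the
per-bp mean CpH level, anchor-strand only by default (`same_strand_only`
pools both). Smoothing is a centered moving average with truncated edge
windows; even window sizes are widened to the next odd size.

Periodicity is the lag of the autocorrelation maximum of the mean-detrended
profile over a lag range — 5..15 bp for the DNMT3a-associated 8–10 bp
signal, 100..300 bp for nucleosome-scale structure — with an optional
permutation null from circular shifts (95th percentile of 200 shifts).

Sample clustering uses per-sample mCpG-proximal (±100 bp) per-offset mean
mCpH vectors (or 1-kb block vectors), pairwise Pearson correlation,
distance 1 − PCC and average linkage (the linkage is configurable; average
is the common choice for correlation distances). The dendrogram is exported
as Newick.

**Coupling-range estimation.** Each CpH is paired with its *nearest*
methylated-CpG anchor (matching the deposition model below) and the
per-offset mean CpH level, covariance and PCC against the anchor level are
computed. The kernel-width estimate interpolates across a ±8 bp central
exclusion zone (which can carry a localised motif spike), smooths (15 bp),
folds the signed sides, subtracts the far-tail baseline and reports the
interpolated half-maximum crossing. The *mean-level* curve is used by
default: under the generative model it is exactly proportional to the
deposition kernel, whereas covariance/PCC-based curves inherit the very
small variance of methylated-CpG anchor levels (sd ≈ 0.06) and are noisy at
desk-scale genome sizes. The PCC curve is still informative qualitatively
(higher within ±100 bp than beyond 200 bp).

## Context and gene analysis

Context summaries are unweighted means per trinucleotide (CAC, CAT, CAA,
CAG, other CpH) and per symmetry class (CpHpG = third base G, CpHpH
otherwise), genome-wide or restricted to ±100 bp of CpGs with level > 0.5.
The hyper-mCpH motif is a 4×6 position frequency matrix over −1..+4 around
CpHs with level > 0.5 (level cutoff, not the binomial call), sequences read
on each site's own strand, windows leaving the chromosome dropped, consensus
ties broken A<C<G<T and flagged.

Gene bodies are TSS..TTS; only genes longer than 1 kb are analysed. The
metagene axis maps body ± 20%-of-length flanks onto 1000 bins; with that
flank fraction the TSS/TTS boundaries fall at bins
$\lfloor 0.2/1.4 \cdot 1000\rfloor = 142$ and
$\lfloor 1.2/1.4 \cdot 1000 \rfloor = 857$ (1-based floor convention).
Sites are binned by base midpoint, which makes minus-strand profiles exact
mirror images. Smoothing is 30 bins — the normalised axis has no fixed bp
scale, so the window is interpreted in bins and exposed as a parameter.
Expression groups are the top/bottom 20% FPKM quantiles with inclusive
ties. The histone overlapping rate is |union(peaks) ∩ body| / body length
(peaks merged first). The gene screen keeps genes with mean gene-body CAG
level > 0.05 ("mCAG level" = mean integrated level over CAG sites, not a
called-site fraction) and overlap rate > 0.5, excluding LOC/Rik placeholder
symbols, and reports the empirical quantile of the 0.05 cutoff so it can be
read as a top-x% statement.

## Synthetic-data generator

The generator is the package's study-condition definition: each mode fixes
the deposition rules the analysis is expected to detect.

**Genome.** I.i.d. bases at GC 0.42 with CpG dinucleotides thinned
(C→T) to an observed/expected ratio of 0.12, emulating mammalian CpG
depletion; without thinning, methylated-CpG anchors would sit ~15 bp apart
and their coupling halos would overlap completely. A 20-kb fully
unmethylated control contig supports non-conversion estimation. Genes are
non-overlapping, log-uniform in length (1–20 kb by default), random strand.

**CpG methylation.** Per CpG dyad (palindromic pair), a high Beta(20, 2)
draw (mean ≈ 0.91) with probability 0.75, else a low Beta(1.5, 28) draw
(mean ≈ 0.05) — the bimodal landscape of real methylomes. 8% of 1-kb
regions are hemi-methylated: every dyad there is high on a randomly chosen
favoured strand and low on the other, giving the block-level strand
asymmetry the hemi analysis consumes.

**CpH deposition.** Each CpH's true level is
`min(bg + A · k(off) · s · w(trinuc) · mult(gene) · L_anchor, 1)` where
`bg` is a per-site Gamma(2, mean 0.02) background (nonnegative by
construction, so the far tail of the coupling curve is not distorted by
clipping), `A = 0.75`, `k` is a Gaussian envelope with half-max at the
kernel width (100 bp) times mode-specific modulations, `s` is 1 on the
anchor's strand and 0.3 opposite (cis preference), `w` the context weight,
`mult` the per-gene expression-coupling multiplier and `L_anchor` the
*nearest* methylated-CpG level. Distance to the nearest anchor only — a
minimal model of processive deposition with no long-range interactions.
Modulations: ESC adds a ×(1 + 3·exp(−(off+4)²/2)) boost at −4 bp; neuron a
(1 + 0.7·cos(2π·off/9)) modulation; DNMT1-KO a 180-bp cosine over a wider
(400 bp) envelope with sparse anchors (mcpg_high_fraction 0.03 — DNMT1 loss
removes maintenance methylation, which is also what makes nucleosome-scale
structure visible). Context weights: ESC CAG 1.0 / CAA 0.4 / CAC 0.25 / CAT
0.2 / other 0.1; neuron CAC 1.0 / CAT 0.3 / CAG 0.25 / CAA 0.2; DNMT3b-KO
suppresses CAG/CAA (0.1/0.08); DNMT3-DKO and somatic modes scale the
amplitude to near zero. The coupling amplitude is deliberately high so the
hyper-methylated CpH class (> 0.5) is populated at desk-scale genome sizes.

**Counts.** Depth n ~ Poisson(15); methylated reads
k ~ Binomial(n, m + (1−m)·ncr) with ncr = 0.005; reads split across three
aligners with weights (0.40, 0.35, 0.25) and 5% per-site per-aligner
dropout; methylated reads partitioned hypergeometrically so pooling the
split exactly reproduces the single table.

**Expression and peaks.** A latent Gaussian chain
expression → H3K36me3 coverage → methylation multiplier with latent
correlations a = 0.7 and b chosen so the planted Spearman
rho(gene mCpH, FPKM) hits `expression_coupling` (ESC +0.4, neuron −0.3,
knockouts 0). The copula correlation is back-computed through
rho_s = (6/π)·asin(r/2) with a fixed 0.95 allowance for anchor-placement
noise in finite gene bodies — an analytic design choice, not a fitted
constant. Because methylation couples to coverage, not to expression
directly, rho(mCpH, overlap) exceeds rho(mCpH, FPKM) by construction.
FPKM is log-normal; peaks are 1–3 disjoint intervals per gene body whose
union covers the planted overlap fraction. SETD2-KO scales peak coverage to
5% and decouples it from expression.

All stages draw from independent child streams of a single seed; the whole
generator, and the pipeline outputs downstream of it, are byte-reproducible
per seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (mapping bias, M-bias,
strand-specific conversion failure), CpG islands and other sequence
heterogeneity, chromatin-domain-scale autocorrelation of methylation,
overdispersion beyond binomial counting noise, aligner-specific systematic
disagreement (the three synthetic aligners differ only by sampling), and
biological replicate variance. Qualitative contrasts recovered here
demonstrate that the pipeline detects the planted structure, not that the
structure exists in any particular organism.

## Problem sizes and test design

Tests and the acceptance script use genome sizes chosen for single-CPU
turnaround: 150–800 kb genomes for profile/motif/context checks, 400 kb for
nucleosome-scale periodicity, 5 Mb with 2000 shorter genes (1.05–3 kb) for
expression-coupling recovery, a four-sample 200-kb cohort for clustering,
and one million flat sites for FDR calibration. The FDR experiment plants a
2% truly methylated fraction (levels uniform in 0.3–0.9) at mean depth 15.
Oracle tests freeze expected values from independent brute-force
reimplementations (binomial summation, per-base bitmaps, window scans,
naive group-bys) on ≤ 1000-element fixtures.

## Known limitations

* The FDR denominator is the real call count at the same threshold; with
  very few real calls the estimate is unstable (reported NaN at zero).
* Strand-oriented profiles assume the anchor CpG's strand is meaningful for
  nearby CpHs; in both-strand probability mode asymmetric features blur.
* The motif PFM counts each site independently; palindromic contexts on
  both strands are counted twice by design.
* `metagene_profile` averages per-gene bin means, so short genes with empty
  bins contribute unevenly at fine bins before smoothing.
* The generator's nearest-anchor deposition ignores multi-anchor additive
  effects; profiles computed with all-anchor window pairing therefore carry
  a mild flat contamination term from non-nearest anchors.
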