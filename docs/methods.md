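# Methods

This note records the models, numerical choices and known limitations of
`chromcouple`. Coordinates are 0-based half-open everywhere; fold
changes are always population A over population B.

## Consensus peaks and qualitative classification

Replicate narrowPeak sets are merged by single-linkage interval union
(any ≥ 1 bp overlap joins two peaks). A merged region is retained when
peaks from at least `min_support` distinct replicates overlap it
(default 2 of 3). This support filter is the package's reproducibility
step; it is deliberately simpler than rank-consistency (IDR-style)
filtering, which operates on peak scores that the downstream analysis
never consumes. Merged peaks lose their caller summits, so the summit of
a consensus peak is defined as the interval midpoint (floored).

The two population consensus sets are pooled by the same union rule, and
each pooled peak is classified `shared` when consensus peaks from both
populations overlap it, `exclusive_A`/`exclusive_B` otherwise. The
overlap predicate is a single base pair; class counts always sum to the
pooled total (asserted at run time). With jittered replicate peaks whose
boundary noise is ≤ 10% of the peak width, pooled peaks map one-to-one
onto true loci and the classification is exact on synthetic data — real
data will contain partially overlapping peaks where single-bp overlap is
a generous criterion; the fraction of such borderline peaks should be
checked before interpreting small exclusive classes.

## Counting and the negative-binomial test

Quantification happens on a fixed peak atlas: count-table feature ids
encode coordinates (`chrom:start-end`) and pooled peaks inherit the
summed counts of the atlas features they overlap. When per-sample
fragment lists are supplied instead, a fragment is assigned to the
single peak containing its midpoint, which avoids double counting.

Both differential branches use one engine. Counts are modelled as

    K_gs ~ NB(mean = s_s · μ_g(pop(s)),  Var = m + α_g m²)

with median-of-ratios size factors s_s (geometric-mean reference over
genes positive in all samples). The gene-wise dispersion α_g is a
method-of-moments estimate from within-group deviations of normalized
counts, clipped at zero, and shrunk with weight w = 0.5 toward the
10%-trimmed mean dispersion across genes. The Wald statistic is
`log2(μ̂_A/μ̂_B)` over its delta-method standard error,

    Var(log2 μ̂_P) = (Σ_{s∈P} 1/s_s / μ_P + n_P α) / (n_P² ln²2).

The reference distribution is Student-t with Satterthwaite effective
degrees of freedom `df = (n_A + n_B − 2)/(1 − w)²` (16 for 3 vs 3 at the
default weight): the shrunk variance estimate mixes a low-df gene-wise
component with an effectively noise-free common component, so neither a
standard normal (anti-conservative at n = 3: ~7% rejection at nominal
5% in our null simulations) nor a raw t with n_A+n_B−2 df (calibrated
but with sensitivity < 0.5 against 4-fold shifts) is appropriate. Under
the simulated null (2,000 features, dispersion 0.1, 3 vs 3) the choice
gives ~5% rejection at α = 0.05 and Kolmogorov–Smirnov uniformity
p-values well above 0.05; against 10% planted 4-fold shifts it reaches
sensitivity ≈ 0.97 with false-discovery proportion ≈ 0.08 at BH-FDR
0.10. These figures are recomputed by the acceptance suite.

Features where one population's mean is exactly zero get a signed
infinite fold change, a one-sided p-value from the finite side, and a
`zero_group` flag; all-zero features are flagged `all_zero` with p = 1.
Nothing is dropped silently. BH adjustment (statsmodels step-up) runs
over all tested features.

Default thresholds: accessibility FDR ≤ 0.10 (optionally with a
|log2FC| ≥ 1 filter, off by default); expression adjusted p < 0.05, plus
the stricter volcano set |log2FC| ≥ 1 and FDR ≤ 0.01.

## Detection threshold and the expression partition

The intergenic background is summarized per sample as the nearest-rank
95th percentile of `log2(count/s_s + 1)` over 5-kb windows
(`rank = ⌈q·n/100⌉`, interpolation-free and deterministic). The pooled
threshold is the maximum over samples — the conservative choice when
samples disagree. A gene is called expressed in a population when the
mean of `log2(normalized count + 1)` across that population's
replicates is strictly greater than the threshold; ties at the boundary
are "not expressed". The package compares gene counts and window counts
on the same normalized-count scale without length normalization; since
the threshold is a quantile of the background this only assumes the
gene/window length ratio is homogeneous, which holds for the synthetic
generator and approximately for fixed-width windows on real data.

## Peak–gene annotation and coupling

Each pooled peak is annotated with the gene whose TSS is nearest to the
peak summit, if within ±150 kb; ties go to the lexicographically
smaller gene id. The signed distance is summit − TSS, sign-flipped on
minus-strand genes so negative always means upstream. Categories:
`tss_proximal` within 1 kb, else `genic` when the summit falls in a gene
body, else `intergenic`. TSS over-representation between the two
exclusive peak classes is a one-sided Fisher test on the 2×2 table
(tss_proximal vs not) × (exclusive_A vs exclusive_B).

Coupling classifies each annotated peak by joint significance at
FDR < 0.1 in both assays: `concordant_A` when both log ratios are
positive, `concordant_B` when both negative, `discordant` when strictly
opposite. A log ratio of exactly zero carries no direction and lands in
`not_significant`. Peaks with no gene in the window are `unassigned`.
Nearest-TSS assignment is a deliberate simplification: it ignores
enhancer–promoter loops and multi-gene regulation, so coupling classes
are hypotheses about the *most plausible* target, not assignments.

## Motif scanning and combination enrichment

Sequences of ±200 bp around A-exclusive summits are scanned with each
PWM on both strands. The score at an offset is the summed log2-odds of
the observed bases against the PWM background; positions containing N
score −∞. A hit requires ≥ 0.8 of the motif's maximum attainable score
(configurable; HOMER's internal thresholds are not reproduced). The
scanner is vectorized but exactly equals exhaustive per-offset scoring
(asserted against a brute-force oracle in the tests).

Enrichment is presence-based: a sequence either contains a motif (≥ 1
hit) or not, matching a sequence-set comparison design. For order-3
combinations, presence requires one hit of each motif inside some
500-bp window (`max(hit ends) − min(hit starts) ≤ span`); for 400-bp
summit windows this reduces to co-presence, and the general span test
only activates on longer sequences. Scanning happens once per
(sequence set, motif); combination statistics reuse the cached hits.
Each combination's 2×2 table (peak vs background × present vs absent)
gets a one-sided (greater) Fisher exact test — enrichment direction
only — and BH adjustment across all C(n,3) combinations. The background
is 20,000 random 400-bp windows drawn uniformly from the genome
(windows with > 10% ambiguous bases are rejected and resampled); a
GC-matched mode is not implemented — with the synthetic i.i.d. genome
GC matching is a no-op, and on real genomes its absence can inflate
enrichment of GC-rich motifs, which users should keep in mind.

Null calibration of the combination test is only observable when the
2×2 tables are populated: sharp consensus-like PWMs essentially never
hit random sequence at a 0.8 threshold, leaving every table empty and
every p-value at 1. The calibration study in the acceptance suite
therefore uses smooth equal-information PWMs (`soft_motif_set`, one
probability profile permuted across bases at every position) at a 0.75
threshold on 200-bp sequences, 4,000 peak-like vs 8,000 background
windows, 50 seeded runs. In that regime the fraction of combinations at
p < 0.05 sits inside the 95% binomial interval around 0.05 and pooled
p-values pass a KS uniformity test at the 1% level. Outside it —
sparse tables, or presence probabilities near 0 or 1 — the exact test
is visibly conservative (discrete p-values), which is a property of
exact conditional tests, not an implementation defect.

## Synthetic data

The generator emulates a two-population sorted-cell study: two
populations × 3 replicates; i.i.d. genome at 45% GC; 400-bp true peak
loci placed on a disjoint slot grid (pitch 2× width), 90% shared and 5%
exclusive per population by largest-remainder rounding; replicate peak
boundaries jittered by ≤ 10% of width. Counts are negative-binomial
(dispersion 0.1 for genes and peaks; low-mean windows at dispersion 0.3
for the intergenic background) with per-sample size factors log-uniform
in [0.5, 2] applied multiplicatively to the means. Gene log2 means are
uniform on [8, 12] — comfortably above the intergenic noise floor
(~log2 4), giving ≥ 4 log2 units of separation for detection — with 10%
differential genes shifted ±2 log2 units (alternating sign), 5%
specific to each population (background-level in the other), and 10%
silent. Exclusive peaks carry a 3-log2-unit accessibility shift toward
their population. A configurable fraction of peaks (default 1.6%) is
coupled: an A-exclusive peak paired with an up-in-A differential gene
whose TSS is placed 0.2–3 kb from the summit; other genes are
rejection-sampled away from coupled summits so the planted gene is
provably the nearest TSS. The planted motif triple's consensus words
are written into 60% of A-exclusive summit windows, one per third of a
300-bp span, on random strands.

What the generator does *not* model: mapping artefacts and blacklist
regions, GC or Tn5 insertion bias, fragment-length structure,
overdispersion heterogeneity across genes, correlated replicates, genes
with multiple isoforms or overlapping bodies, and real motif
redundancy. Passing the acceptance suite therefore demonstrates that
the algorithms are implemented correctly and control their error rates
under their stated model — not that the model captures every property
of real sequencing data.

One global seed fans out to fixed per-stage child seeds
(`numpy.random.SeedSequence(seed, spawn_key=(stage,))`), so each stage
is individually reproducible and a dataset is byte-identical under a
fixed seed.

## Problem sizes and determinism

The bundled default dataset is 2 chromosomes × 3 Mb, 3,000 peaks, 2,000
genes, 1,000 intergenic windows, 12 motifs and a 20,000 × 400-bp
background; the full pipeline runs in about a minute on one CPU.
Simulation-based checks in the test suite use 2,000 genes / 5,000 peaks
for error-control measurements and 50 seeded runs for null calibration
— sizes at which binomial confidence intervals around the tested rates
are a few percentage points wide. Pipeline outputs are deterministic
given the configuration and seed; reruns are byte-identical except for
the config echo inside `summary.json` when paths differ.

## Known limitations

* The NB Wald test is a documented approximation, not a reimplementation
  of DESeq2/edgeR numerics (no Cook's distance filtering, no
  moderated-LFC shrinkage, no independent filtering of low-count genes).
* Single-bp overlap classification can over-merge adjacent peaks on
  dense real data.
* Nearest-TSS coupling ignores long-range regulation.
* Background sampling is not GC- or repeat-matched.
* The per-sample detection threshold assumes the intergenic windows are
  a fair noise sample; copy-number variation or unannotated
  transcription would bias it upward.
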