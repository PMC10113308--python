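# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `triomics`. Genotypes
are written E (maternal parent), G (paternal parent) and F (their hybrid).

## Dominance classification

The core procedure classifies each differential feature by the relation of
the hybrid's level to the two parents. For every genotype pair a verdict
(`<`, `=`, `>`) is produced; a pair is declared different only when both a
two-sample Student *t*-test and a Tukey HSD over the three genotypes reject
at α = 0.05. The conjunction is deliberately conservative: it makes the
verdicts stable under either test's marginal failures, at the cost of some
power. The Tukey step uses the studentized-range distribution with k = 3
groups and df = N − 3 pooled degrees of freedom (Tukey–Kramer standard
errors when replicate numbers differ). Significance is decided against the
cached critical value, which keeps the per-feature cost trivial and the
whole 1,200-feature classification under a second. Welch *t*-tests are
available via `equal_var=False`.

The verdict triple maps onto twelve categories via an explicit decision
table; the five collapsed groups are additive {I, XII}, paternal dominant
{II, XI}, maternal dominant {IV, IX}, transgressive up {III, VII, X} and
transgressive down {V, VI, VIII}. For transgressive categories with
unequal parents, VII/V denote the configuration with E below G and X/VIII
the mirror; downstream analyses use only the group, so this sub-labelling
is a deterministic convention rather than a scientific claim. Verdict
combinations outside the table (e.g. non-transitive Tukey outcomes, or
`F≠E`, `F≠G` in opposite directions with `E=G`) are reported as
`unclassified`. Only features differential in at least one pairwise
contrast of the stage are classified; everything else is `unclassified` by
construction.

**Scale.** Expression tests run on log2(normalized count + 1). On the raw
scale the NB variance grows quadratically with the mean, so the pooled
Tukey MSE is dominated by the highest-expressed genotype and contrasts
among the lower-expressed genotypes become undetectable regardless of
their fold change; the log transform approximately stabilizes the variance
and restores those contrasts. Reported genotype means are always on the
original scale. Methylation levels are proportions in [0, 1] and are
tested untransformed.

## Differential calling

Size factors are median-of-ratios: per feature, the geometric mean across
samples is the reference (features containing any zero are excluded from
reference construction); a sample's factor is the median ratio of its
counts to the reference. The estimator assumes the planted/observed
changes are roughly balanced across samples — with strongly one-sided
composition the factors absorb part of the signal, which is inherent to
this normalization, not an implementation artifact. When no feature is
nonzero in all samples the function raises rather than silently switching
to a pseudo-reference.

The built-in caller is a per-feature Wald test on the log difference of
group means of normalized counts, with delta-method standard errors under
the NB variance μ + αμ² and a per-feature method-of-moments dispersion
α̂ = max((s² − x̄)/x̄², 10⁻⁸) averaged over the two groups (no shrinkage).
The Wald statistic is referred to a *t* distribution with n₁ + n₂ − 2
degrees of freedom: with 3 replicates per group the normal reference is
anticonservative, and the *t* reference keeps the all-null false-positive
rate at or below nominal (verified by simulation in the test suite).
Groups with zero mean receive a 0.5 pseudo-count on the mean. BH
adjustment is applied within each contrast; features are differential at
padj < 0.05. The stage is pluggable: any table in the DifferentialResult
TSV dialect can replace the built-in caller.

## DMR calling and methylation dominance

Cytosine reports are filtered to positions whose methylation state was
observed at least 3 times in a sample, then pooled per genotype into
1,000-bp bins anchored at coordinate 0 on each chromosome, separately per
context (CpG, CHG, CHH). For a genotype pair, a bin is a DMR candidate
when (i) each genotype has ≥ 4 covered cytosines in the bin, (ii) the
pooled methylation-proportion difference satisfies |Δ| ≥ 0.4, and (iii)
the two-proportion score test gives p < 0.01. The score statistic uses the
pooled proportion's variance; its square equals the Pearson chi-square of
the 2×2 reads table, which the tests verify to 10⁻¹⁰. The minimum cytosine
count is applied per genotype (the stricter of the two possible readings).
Candidate bins separated by at most `min_gap` bp with the same direction
merge (the default gap 0 merges only touching bins); merged statistics are
recomputed on pooled counts and re-audited against all three thresholds —
in the measure-zero case where re-weighting flips the merged region below
a threshold, the constituent bins are emitted unmerged so that every
emitted DMR satisfies the thresholds exactly. DMRs are called in CpG and
CHG contexts by default; CHH calling is available behind an explicit flag.

Methylation level dominance (MLD) applies the dominance classifier to
replicate-level methylation proportions inside each DMR (reads pooled over
the DMR's bins per replicate), with 2 replicates per genotype. The
transgressive groups read as hyper-/hypomethylation.

## CpG islands

A 100-bp window passes when GC ≥ 50 % and observed/expected CpG
= CpG·L/(C·G) ≥ 0.6 (windows with zero C or G, or containing N, fail).
Overlapping passing windows merge; the merged span is re-evaluated on its
full length and kept only when it still passes with length > 200 bp.
Boundaries therefore carry up to one window of slack around a planted
island, which the tests account for.

## sRNA clusters

Classification consumes upstream-produced evidence: the primary-read
length histogram, a per-cluster unpaired-base count and a hairpin flag.
A cluster is a miRNA candidate when ≥ 80 % of primary reads are 20–24 nt,
unpaired bases < 5, and the flag is in {Y, N15, N14, N13}; otherwise it is
a putative 24-nt siRNA when ≥ 80 % of primary reads are exactly 24 nt. The
miRNA rule is applied first, so a cluster meeting both is a miRNA
candidate. Clusters with zero counts in all samples are removed before
classification. Structure prediction itself is out of scope.

## Integration

A putative epiallele is a differential gene with an additive or
parent-dominant expression group and at least one DMR overlapping its body
or 1-kbp strand-aware promoter whose MLD group carries the same label.
Direction concordance (hyper vs up) is intentionally not required — both
proportional and inverse expression–methylation couplings occur — so
"corresponding pattern" means "same group". Proximity association builds,
per feature class, the 2×2 table of flank membership (5-kbp gene or DEG
flanks, gene body excluded; membership means a gap strictly below 5,000 bp)
against differential status, tested by Pearson chi-square without
continuity correction and BH-adjusted across the family; tables with any
expected cell below 1 are skipped with a note. Expression–methylation
correlation is Kendall τ-b (tie-corrected, asymptotic p) over gene ×
genotype observations within a stage, reported separately for gene-body
and promoter methylation; constant inputs yield a missing τ rather than an
error. DMR composition assigns each DMR to all overlapping annotation
classes (promoter, exon, intron, repeat — not mutually exclusive) and
reports distance to the nearest gene, ties broken toward the smaller gene
ID.

## Segments and CNVs

The genome is tiled into non-overlapping 500-kbp windows; a window is a
candidate segment when more than 20 differential genes (by annotation
midpoint) fall in it for some genotype × stage. The up/down bias is
log2((n_up + 0.5)/(n_down + 0.5)) — the pseudo-count makes the score
finite and symmetric where a raw ratio would be undefined. Bias values are
Z-normalized within the segment across its genotype × stage cells, and a
candidate is retained when the Z range across genotypes reaches 1.5 in at
least one stage. This explicit rule replaces visual heatmap clustering and
is the largest formalization in the package; the threshold is configurable
and retention is monotone in it. Partial last windows are kept and
flagged.

CNV calling aggregates windowed depth to 25-kbp windows, excludes depths
above 100 from the genome-wide mean/SD estimate, and calls windows below
mean − 1 SD deletions and above mean + 1 SD duplications, merging adjacent
same-type windows. The 1-SD rule implies a ~32 % two-sided tail on
undisturbed data — the caller is a coarse screen for large, strong events
(0.1× deletions, 2× duplications), not a general SV caller. Genome-wide
(not per-chromosome) moments are the default; this makes an almost-entirely
deleted genome undetectable in principle, which is the documented
trade-off of the rule.

## Synthetic data model

The generator plants machine-readable truth for every stage from one seed;
independent deterministic substreams per stage make each output
reproducible bin-for-bin and byte-for-byte.

* **Counts.** Replicate counts are gamma-Poisson (negative binomial) with
  constant dispersion α = 0.05 across features (variance μ + αμ²) and
  3 replicates per genotype. Per-feature base means are lognormal around
  50 (σ_log = 0.4). A feature's category fixes the (E, F, G) mean
  multipliers, with distinct levels drawn from {1, f, f²} at fold change
  f = 4 so that every detectable contrast carries the full configured
  effect size. The default planting is balanced across the twelve
  categories, which also keeps the median-of-ratios assumption satisfied.
* **Methylome.** Contexts are derived from the generated genome sequence
  (both strands), so the CpG-island scanner and the methylome share one
  genome. Background methylation is 0.8/0.5/0.2 for CpG/CHG/CHH, mirroring
  the canonical plant ordering of context methylation levels. Planted DMRs
  occupy whole 1-kbp bins in the CpG context with genotype proportions
  from {0.3, 0.55, 0.8} (low, mid, low + Δ with Δ = 0.5) following the same
  12-category taxonomy; per-cytosine depth is Poisson(30) and methylated
  reads are Binomial(depth, p), with 2 replicates per genotype.
* **Coverage.** Depth per 1-kbp window is Poisson(30), multiplied inside
  planted CNVs (0.1× deletions, 2× duplications aligned to the 25-kbp
  grid).
* **sRNA.** Cluster length histograms, unpaired-base counts and hairpin
  flags are planted per class; cluster counts reuse the NB trio model with
  categories cycling through the taxonomy.

What the generator does **not** emulate: read sequences and alignment
artifacts, bisulfite conversion failure, positionally autocorrelated
methylation, TE-driven methylation structure, isomiR variation, overlapping
or nested gene models, and biological replicate effects beyond sampling
noise. Passing the planted-truth tests therefore demonstrates that the
statistical machinery recovers the planted effects under idealized noise;
it does not certify performance on real libraries, where dispersion varies
per feature, composition is unbalanced, and methylation is spatially
correlated.

## Problem sizes and defaults

The standard verification conditions are 1,200 count features (100 per
category), two 150-kbp chromosomes with 36 planted DMR bins for the
methylome, a 2-Mbp chromosome for CNV recovery and four 2.5-Mbp
chromosomes for the null CNV tail, chosen so the full test suite and the
acceptance script each complete in well under a few minutes while leaving
every rate estimate enough events to be stable (e.g. ≥ 50 planted DMR
regions per pairwise truth set). All thresholds surfaced above are
parameters of `PipelineConfig`/`SimulationConfig` with the defaults stated
here.

## Known limitations

* The t/Tukey conjunction with 2 methylation replicates has limited power
  for subtle MLD patterns; planted Δ = 0.5 at 30× is comfortably detected,
  but smaller deltas will inflate `unclassified`.
* The NB Wald caller does not implement dispersion shrinkage, outlier
  handling or independent filtering; for real data an external caller's
  table can be supplied instead.
* `min_cytosines` counts covered cytosines per genotype after pooling
  replicates; alternative readings (joint, per replicate) are not offered.
* The segment Z-range rule is a formalized stand-in for judgment-based
  clustering; its threshold has no inferential calibration.
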