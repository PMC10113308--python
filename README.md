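# triomics

Dominance analysis of gene expression, small-RNA abundance and DNA
methylation in parent–parent–hybrid trios.

When two inbred lines are crossed, each differential feature in the trio —
a gene, a miRNA or siRNA cluster, or a differentially methylated region
(DMR) — can be placed relative to the maternal parent *E*, the paternal
parent *G* and the hybrid *F*. `triomics` implements the full analysis a
hybrid-transcriptomics/epigenomics study needs to do this at desk scale,
plus a synthetic-data generator that plants known truth into every layer so
each stage of the pipeline is verifiable end to end. It is aimed at plant
(and other) geneticists studying heterosis and parental dominance in
hybrids, and at methods developers who need a fully testable reference
implementation of this analysis chain.

## The classification at the core

For each differential feature, replicate-level values (normalized counts
for expression, methylation proportions for DMRs) are compared between all
three genotype pairs. A pair is declared different only when **both** a
two-sample Student *t*-test and a three-group Tukey HSD (studentized range,
df = N − 3) reject at α = 0.05. The verdict triple
(v(F,E), v(F,G), v(E,G)) then maps to one of twelve categories, collapsed
into five groups:

| group | categories | meaning |
|---|---|---|
| additive | I, XII | F between the parents, all three differ |
| paternal dominant | II, XI | F = G ≠ E |
| maternal dominant | IV, IX | F = E ≠ G |
| transgressive up / hyper | III, VII, X | F above both parents |
| transgressive down / hypo | V, VI, VIII | F below both parents |

Around this sit the supporting stages:

- **Differential calling** — median-of-ratios size factors and a
  per-feature negative-binomial Wald test (method-of-moments dispersion,
  BH adjustment, padj < 0.05); the stage is pluggable, so an externally
  produced differential table in the same TSV dialect can be slotted in.
- **DMR calling** — per-cytosine reports (Bismark CX dialect) pooled into
  1-kbp bins per CpG/CHG/CHH context; two-proportion score test with
  thresholds p < 0.01, |Δ| ≥ 0.4, ≥ 4 covered cytosines per genotype;
  adjacent same-direction bins merge. The same 12-category taxonomy is then
  applied to replicate-level DMR methylation (methylation level dominance).
- **CpG islands** — sliding-window Gardiner-Garden & Frommer criteria
  (GC ≥ 50 %, length > 200 bp, observed/expected CpG ≥ 0.6).
- **sRNA clusters** — miRNA candidates (≥ 80 % of primary reads at
  20–24 nt, < 5 unpaired bases, hairpin flag Y/N15/N14/N13) vs putative
  24-nt siRNAs (≥ 80 % of reads exactly 24 nt, no miRNA flags).
- **Integration** — putative epialleles (differential genes whose
  expression dominance group matches an overlapping gene-body/promoter
  DMR's methylation dominance group), chi-square proximity association
  with 5-kbp gene flanks, Kendall τ-b expression–methylation correlation,
  DMR feature composition and distance-to-gene distributions.
- **Segments and CNVs** — 500-kbp windows with > 20 DEGs scored by
  log2 up/down bias and within-segment Z-range; 25-kbp read-depth windows
  beyond mean ± 1 SD (depths > 100 excluded from estimation) called as
  deletions/duplications and intersected with the segments.

## Worked example

```python
from triomics import simulate, diffexpr, dominance
from triomics.pipeline import classify_stage

cfg = simulate.SimulationConfig(
    seed=42,
    n_features_per_class={**{c: 25 for c in simulate.CATEGORIES}, "null": 100},
)
matrix, truth = simulate.simulate_trio_counts(cfg)
counts = diffexpr.filter_zero_features(matrix.counts)
norm = diffexpr.normalized_counts(counts)
de, _ = diffexpr.de_features_any_contrast(matrix, cfg.stage, norm=norm)
calls = classify_stage(matrix, norm, de, cfg.stage, "mRNA", 0.05)
print(dominance.dominance_summary(calls).round(1).to_string(index=False))
```

```
stage omic  n_classified  additive  maternal_dominant  paternal_dominant  transgressive_up  transgressive_down
 OS15 mRNA           300      16.3               17.0               16.3              25.3                25.0
```

300 of the 400 simulated features are classified; the five group
percentages match the planted composition (each of the twelve categories
was planted 25 times, so e.g. the two additive categories make up
2/12 ≈ 16.7 % of classified features, the three transgressive-up ones
3/12 = 25 %). A single call shows the verdict triple behind a group label:

```
feature_id stage omic vFE vFG vEG category             group  mean_E  mean_F  mean_G
gene_00100  OS15 mRNA   =   >   >       IV maternal_dominant   141.2   116.9    29.7
```

The hybrid is indistinguishable from the maternal parent (`vFE` `=`) and
both sit above the paternal parent — category IV, maternal dominant, which
is exactly what was planted for this feature. Comparing all calls against
the truth sidecar gives a group recovery of 97.7 % among differential
features on this run.

The same analysis is available from the shell:

```sh
triomics run --seed 42 -o results/demo          # full pipeline
triomics simulate -c config.yaml -o sim/        # inputs + truth sidecars
triomics de --counts sim/counts.tsv --samples sim/samples.tsv --stage OS15 -o de.tsv
```

Subcommands: `run`, `simulate`, `de`, `dominance`, `dmr`, `mld`, `srna`,
`islands`, `segments`, `cnv`, `integrate`.

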