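# flydelay

Sex-by-age differential expression and male-delayed expression analysis for
*Drosophila melanogaster* brain bulk RNA-seq counts.

Adult fly brains are sexually dimorphic, and part of that dimorphism is
temporal: some genes change expression in females between 3 and 7 days
post-eclosion and make the same change in males one age interval later,
between 7 and 14 days. `flydelay` implements the complete desk-scale
analysis for detecting this pattern from a gene × sample count matrix:

* **Normalization** — median-of-ratios size factors: for sample *j*,
  `sf_j = median_g ( K_gj / (∏_j K_gj)^(1/n) )` over genes with positive
  counts in every sample.
* **Differential expression** — per-gene negative-binomial Wald tests
  (variance `μ + α μ²`, log link, size-factor offsets) over all 15 pairwise
  comparisons of the 2 sexes × 3 ages design (6 within-sex, e.g. `F3v7`;
  9 between-sex, e.g. `F3vM3`), with moment-plus-trend dispersion
  estimation, empirical-Bayes LFC shrinkage and Benjamini–Hochberg
  adjustment. Genes are called DE at raw p < 0.05 or adjusted p < 0.1.
* **QC** — sample PCA on log2(normalized + 1) with robust
  (median + k·MAD) outlier flagging against sex-age group centroids.
* **Delay detection** — per gene and sex, group mean trajectories are
  scaled to a joint maximum of one; interval slopes are divided by the
  interval length in days (÷4 for 3→7, ÷7 for 7→14) and classified as flat
  (|slope| ≤ 0.05), rising (> 0.05) or dropping (< −0.05). Among genes DE
  in both `F3v7` and `M7v14`, delayed upregulation is female =
  (rising, flat) with male = (flat, rising); delayed downregulation is the
  mirror image.
* **Enrichment** — Fisher's exact test for X-chromosome enrichment of DEG
  sets against a detected-annotated background, gene-set
  over-representation (GMT input), and Wang-measure semantic similarity
  over an ontology DAG with hierarchical clustering of enriched terms.
* **Simulation** — a seeded negative-binomial generator that plants
  sex-biased, delayed, single-sex and age-monotone gene classes with known
  trajectories, size factors and X-linkage, so every stage can be verified
  against ground truth.

## Worked example

Simulate a 2,000-gene dataset under the default design (2 sexes × 3 ages ×
3 replicates) and run the full pipeline:

```bash
flydelay simulate --n-genes 2000 --seed 7 --outdir sim
flydelay all --counts sim/counts.tsv --design sim/design.csv \
             --annotation sim/annotation.tsv --seed 7 --outdir results
```

The run prints stage transitions and writes `results/report.json`. For this
seed the report contains:

```
qc:    samples_removed = ['M14_r1'], variance_fraction = [0.358, 0.155]
de:    F3vM3 297 DEGs (p_raw<0.05), 223 (p_adj<0.1)
       F3v7  185 DEGs (p_raw<0.05); M7v14 179 DEGs (p_raw<0.05)
delay: 105 candidate genes (DE in both F3v7 and M7v14),
       75 called delayed-up, 11 delayed-down, LFC correlation r = 0.947
```

Reading the numbers: one sample sat beyond the median + 5·MAD centroid
distance in PC1/PC2 and was removed; the first two components explain 36%
and 16% of the variance. Of the genes DE in both the female early interval
and the male late interval, 75 show the rising-then-flat (female) /
flat-then-rising (male) signature of delayed upregulation, and the two
comparisons' log2 fold-changes are strongly positively correlated — the
planted male delay, recovered. Per-comparison DE tables
(`de_*.tsv`), slopes, calls and enrichment tables are written next to the
report.

Every subcommand (`simulate`, `qc`, `de`, `delay`, `xenrich`, `ora`,
`all`) is also available as a library function; see the module docstrings.

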