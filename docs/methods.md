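# Methods

This note documents the statistical model, the simulator, the numerical
choices, and the places where the design was genuinely open and a choice
had to be made. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Count model and differential expression

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean `sf_j · q_gc(j)` and variance `μ + α_g μ²`, where `sf_j` is the
sample's size factor, `q_gc` the gene's mean on the normalized scale in
sex-age group *c*, and `α_g` the gene-level dispersion.

**Size factors** are classic median-of-ratios: the per-gene reference is
the geometric mean across samples, genes with any zero count are excluded
from the reference set, and each sample's factor is the median of its
count/reference ratios. There is no pseudo-reference fallback: when no
gene is positive everywhere the estimator refuses loudly, because a
silent fallback changes the estimand.

**Dispersion** is estimated by method of moments on normalized counts —
`α̂ = max(0, (s² − m̄)/m̄²)` with `s²` the within-group variance pooled
over all six sex-age groups — followed by shrinkage toward a fitted
mean-dispersion trend `α(m) = a0 + a1/m`. Two details matter at three
replicates per group:

* The trend is fitted by least squares with a deliberately *loose* outlier
  trim (10× the median absolute residual). The raw moment estimates are
  right-skewed; an aggressive trim cuts the upper tail asymmetrically and
  biases the trend low, which in turn inflates Wald type-I error.
* The shrinkage weight is adaptive, in the empirical-Bayes spirit:
  `w_trend = var_sampling / (var_sampling + var_signal)`, with the
  sampling variance of the moment estimate approximated from the
  chi-square distribution of the pooled variance
  (`var(α̂) ≈ 2(1/m + α_trend)²/df`) and the between-gene signal variance
  estimated robustly (MAD) from the residuals around the trend. With 12
  within-group degrees of freedom this pulls the noisy low tail of the
  raw estimates up to the trend — the information sharing that keeps the
  tests calibrated — while leaving high-replicate designs essentially
  unshrunk. The test suite verifies both calibration (null rejection rate
  0.05 ± 0.02 per comparison) and recovery (known α = 0.2 recovered
  within [0.15, 0.25] at 20 replicates).

**Wald tests.** The two-group log-link GLM with a group indicator
decomposes into two independent one-parameter fits, so each group's
log-mean is fitted by Newton iteration (≤ 25 steps, step tolerance 1e-8,
steps clipped to ±10) with log size-factor offsets. The log2 fold-change
is the difference of fitted log-means over ln 2; its standard error comes
from the summed inverse expected Fisher informations `I = Σ μ/(1+αμ)`;
p-values are two-sided normal tails of LFC/SE. Degenerate genes never
emit ±∞: all-zero in both groups gives NaN effect sentinels with p = 1
(no evidence either way), all-zero in one group gives NaN effect and NaN
p (a boundary estimate with no finite Wald statistic), excluded from BH
and propagated as NaN. A pydeseq2 run on the same counts serves as an
independent cross-check in the test suite (LFC correlation > 0.99); it is
never the implementation.

**LFC shrinkage** uses a single zero-centred normal prior with variance
τ² fitted by marginal maximum likelihood (`lfc_g ~ N(0, τ² + se_g²)`
marginally; bounded scalar optimization over log τ²). The posterior mean
`lfc · τ²/(τ² + se²)` guarantees |shrunk| ≤ |MLE| with the sign preserved.
This deliberately replaces heavier mixture-prior machinery; the tests
verify the qualitative contract (MSE against planted truth no worse than
the MLE) rather than equivalence to any particular package.

**Multiple testing** is Benjamini–Hochberg per comparison (statsmodels
step-up behind the module surface), with NaNs excluded from ranking and
propagated. DEG calling uses the dual thresholds raw p < 0.05 and
adjusted p < 0.1 throughout; the adjusted threshold matches the 0.1
target FDR convention, the raw threshold trades false negatives against
false positives for pattern-level analyses.

**Orientation conventions**, recorded in every result: within-sex
comparisons are later-age vs earlier-age (positive LFC = rises with age);
between-sex comparisons are female vs male (positive LFC = higher in
females).

## QC

PCA operates on log2(normalized + 1) with per-gene centering — not a
variance-stabilizing transform; this is a fidelity caveat, chosen for
transparency and zero tuning. Component signs are fixed by making each
component's largest-magnitude loading positive. A sample is flagged as an
outlier when its Euclidean distance from its sex-age group centroid in
PC1/PC2 exceeds median + k·MAD (k = 5 by default) of all such distances.
The rule is this package's own definition of "PCA-identified outlier";
it is robust at three replicates per group but, like any robust cutoff on
18 skewed distances, can flag a clean sample occasionally — flagging and
removal are therefore separate explicit steps, and the flag table always
reports the distances. Note also that a severe outlier drags its own
group centroid, so its two siblings can exceed the threshold with it.

## Delay detection

Per gene, the six group means are scaled by their joint maximum (one
shared scale for both sexes, so cross-sex comparisons of slope magnitude
are meaningful; per-sex scaling is available as a switch). Interval
slopes on the scaled values are divided by the interval length in days —
÷4 for 3→7, ÷7 for 7→14 — and classified with the fixed cutoff 0.05:
rising above, dropping below −0.05, flat otherwise. The boundary
|slope| = 0.05 is assigned to flat: the strict inequalities of the
classification rule leave it unassigned, and the conservative side (fewer
delay calls) was chosen. An optional mode-gap estimator (Gaussian KDE on
pooled |corrected slopes|, cutoff at the first density minimum between
modes) can replace the fixed cutoff.

Candidates are the intersection of the `F3v7` and `M7v14` DEG sets at raw
p < 0.05 (union available by flag). Delayed-up requires female pattern
(rising, flat) and male pattern (flat, rising); delayed-down the mirrored
(dropping, flat)/(flat, dropping). The two call sets are mutually
exclusive by construction. Slopes are computed on group means, not
per-replicate fits, and the detector template is defined for exactly two
intervals — more ages raise an error rather than silently generalizing.

## Simulator

The generator emulates a pooled-brain bulk design: 2 sexes × 3 ages
(3, 7, 14 days) × 3 replicates, ~5,000 genes, log-normal baseline means
(median ≈ 55 counts), per-sample size factors with 0.3 log-sd, and
per-gene NB dispersion drawn uniformly from (0.02, 0.1). The dispersion
default reflects the low biological variability expected of samples
pooled from ~100 brains; it was set so that the Wald tests have
non-trivial power at three replicates, and the acceptance checks that use
other dispersion regimes (e.g. the null-calibration run at α ∈
[0.05, 0.2]) pass theirs explicitly. Planted classes: `sex_biased`
(constant ±effect_lfc offset, direction split configurable, optionally
restricted to a subset of ages to emulate age-specific dimorphism),
`delayed_up`/`delayed_down` (step trajectories (low, high, high) vs
(low, low, high) and mirrors — step-like rather than linear because the
delayed class is defined by a change interval followed by a stable one),
`female_only_change`/`male_only_change` (distractors for the detector)
and `age_monotone`. Default planted fractions are 10% sex-biased, 4%
delayed-up, 1% delayed-down, remainder null. X-linkage is assigned with
probability 0.17 (approximately the fly X gene share), with the odds
multiplied for sex-biased genes to emulate X-enrichment of sex-biased
expression. All randomness flows through one seeded generator.

What the simulator does **not** emulate: GC/length bias, batch effects,
correlated genes, count outliers of the kind heavy DE frameworks impute,
or any biological variance structure beyond the NB dispersion knob.
Passing recovery tests therefore demonstrate correctness of the
implementation under its own model, not performance on real libraries.

## Enrichment

Fisher's exact tests are one-sided ("greater") by default — the questions
asked are over-representation questions — with two-sided available. The
odds ratio is the sample ratio ad/bc with an ∞ sentinel on zero
denominators. Over-representation analysis intersects each set with the
background before testing and BH-adjusts across tested sets; the
proprietary multiple-testing scheme of web enrichment tools is not
reimplemented, and outputs say so. The X-enrichment background is the
detected-annotated gene set (optionally X-restricted).

Wang semantic similarity is computed exactly: S-values by dynamic
programming upward from each term (multiple parents take the maximum over
paths), similarity as the shared-ancestor S-value sum over the two terms'
total S-values. Edge weights default to 0.8 (is_a) and 0.6 (part_of).
Term clustering cuts an average-linkage tree on 1 − similarity at k = 9
clusters by default; gene-level LFC heatmap clustering uses Ward linkage
on Euclidean distances. Tie-breaking follows scipy's deterministic
nearest-neighbor-chain order, which is what makes repeated runs
identical.

## Pipeline determinism and degenerate inputs

One global seed fans out to per-stage child seeds via a stage-name CRC,
so any stage can be reproduced in isolation. All real numbers in output
tables are formatted with six significant digits, making byte-identical
reruns achievable and verified. Degenerate inputs have defined behavior
throughout: empty designs, unknown sex tokens, ragged or fractional count
tables, cyclic ontologies and overlapping contrast groups all raise typed
errors (mapped to distinct CLI exit codes); all-zero genes carry
degenerate flags through the slope classifier rather than NaN slopes
crashing downstream.

## Problem sizes

The verification suite uses 2,000–5,000-gene simulations with 3
replicates per group (50–100 replicates where a law-of-large-numbers
check needs them), exhaustive enumeration for exact-test validation up to
table total 12, and 1,000 random vectors for the BH oracle — sizes at
which every check runs in seconds while leaving the estimators in the
small-sample regime the design targets.

## Known limitations

* The DE core is a faithful NB Wald implementation but not a clone of any
  specific framework: no Cox–Reid dispersion adjustment, no independent
  filtering, no count-outlier replacement (an optional mean-count filter,
  default off, stands in). Gene-for-gene agreement with such frameworks
  is not a goal; rank agreement is verified by cross-check.
* The delay detector classifies group-mean trajectories; it does not
  model within-group uncertainty of the slopes themselves beyond the DEG
  membership requirement.
* `lfc_correlation` reports plain Pearson r; LFC estimation error in both
  coordinates attenuates it, which is acceptable for the sign/strength
  statements made here.
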