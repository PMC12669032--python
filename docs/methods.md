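# Methods

This note documents the statistical procedures the package implements, the
synthetic data they are validated on, the numerical choices made where the
design was genuinely open, and what the validation does and does not show.

## Growth metrics

A well's fitness proxy is the area under its OD600-vs-time curve after the
curve's minimum is shifted to zero. The trapezoid rule is applied to the
observed time stamps without resampling; it is exact for piecewise-linear
signals, and on hourly data any smoother quadrature would change the value
by less than typical reader noise. Population doublings are
`log2(od_final / od_initial)` on absolute (uncorrected) OD, with both
endpoints floored at 0.01 OD so blank-level readings cannot explode the
logarithm (the floor is our choice; results are insensitive to it between
0.005 and 0.02 for any culture that actually grew). Logistic fits use
`N(t) = K / (1 + ((K−N0)/N0) e^(−rt))` with deterministic initial guesses
(N0 = first OD, K = max OD, r = 4 / time of half-maximum) and report
`converged=False` — not an exception — for flat or unfittable curves
(dynamic range below 0.05 OD by default).

## Monoculture hit calling

Per plate, the z-score compares each treatment well's raw AUC with the
median and sample standard deviation of the plate's vehicle-control (DMSO)
wells; the normalized AUC divides by the control median. The z→p
conversion is one-sided toward inhibition: the screen calls only growth
inhibition, so compounds that stimulate growth get p > 0.5 by
construction (a two-sided option exists). BH correction runs per strain ×
replicate across the compound library, with the denominator fixed at the
library size even when fewer compounds were assayed for a strain.
Replicate significance requires P_adj < 0.05 and normalized AUC < 0.8; a
compound × strain hit requires ≥ 2 of 3 significant replicates. This
two-layer rule is what suppresses false positives: on pure-null plates
the compound-level hit rate is far below the per-replicate 5% FDR because
a false call must both pass the effect-size filter and recur in a second
replicate.

Edge correction (for plate layouts with systematic row/column gradients)
is a multiplicative median polish: rows and columns are iteratively
rescaled (3 sweeps) so their medians match the plate median, preserving
the overall plate scale — a uniform plate is returned unchanged and a
single row inflated by a constant factor is corrected exactly. Dye-footprint
and empty wells are excluded from every statistic. Negative normalized
AUCs (possible after edge correction) are clamped to zero before
effect-size comparisons.

The MIC rule is literal: the lowest tested concentration whose normalized
metric falls below 0.1, with no monotonicity repair, right-censored at the
highest dose. Validation concordance counts a main-screen hit as confirmed
when any validation concentration at or below the main dose independently
satisfies the replicate-significance rule.

## Arrayed mutant screen

Each mutant's AUC is divided by the plate median (rAUC), assuming most
mutants on a plate are phenotypically neutral; the median of rAUCs on a
plate is exactly 1 by construction. Technical-replicate plates are
averaged first and the run-level means form the arms of a two-sided Welch
t-test; the effect size is the nrAUC (mean treated rAUC / mean control
rAUC). Hits use the raw p < 0.05 with |nrAUC − 1| > 0.2; BH-adjusted
p-values are reported alongside for transparency. Mutants whose control
rAUC falls below 0.1 (failed growth in vehicle) are excluded from testing.

A caution this package makes measurable: with only two run-level values
per arm, the Welch degrees of freedom approach 1 and even very large
t-statistics give p near 0.05, capping single-mutant detection power at
roughly 0.93 for a 50% conditional growth reduction under 5% well noise
(measured by simulation). Screens needing per-mutant certainty should run
a third replicate.

## Pooled transposon fitness

Insertion-site counts are depth-normalized by the trimmed total read
count: per sample, the mean of nonzero site counts after discarding the
top and bottom 5% of nonzero values, scaled to the across-sample grand
trimmed mean. Sites outside the central 80% of a coding region
(fractional offset f = (pos − start)/(end − start + 1) outside
[0.1, 0.9)) are masked, and normalized counts are summed per gene; genes
with no retained site are reported untestable rather than given p = 1.

The per-gene test permutes whole samples between the condition and
control arms; the statistic is the difference of per-arm mean counts, and
the two-sided p is the fraction of permuted |statistic| ≥ |observed|,
with the observed arrangement included in numerator and denominator. When
the number of distinct arm assignments C(n1+n2, n1) is at most the
permutation budget (20,000 by default) the enumeration is exhaustive and
the p-value is deterministic; otherwise assignments are sampled with a
seeded generator and the p is floored at 1/n_perm. Log2 fold changes use
a pseudocount of 1 on arm means; the optional doublings correction
rescales log2FC by G_ctrl/G_cond to remove global growth-extent bias
(the per-doubling rescaling is our documented stand-in for the post-hoc
correction concept; no published closed form exists for it). Hits require
P_adj < 0.05 and |log2FC| > 0.25; pathway enrichment of the hit set uses
one-sided Fisher exact tests with BH correction across terms.

Sample-level permutation has a hard resolution limit: the smallest
attainable p is 2/C(n1+n2, n1), which at 2–3 replicates per arm is
0.1–0.2, so BH-adjusted significance is unreachable no matter how strong
the effect. The calibration and recovery simulations therefore use 8 + 8
samples (12,870 distinct assignments, enumerated exhaustively), a design
at which the p-value grid is fine enough both for near-uniform null
p-values and for P_adj < 0.05 hit calls. Real screens run at 2–3
replicates should use a finer-grained permutation scheme (e.g.
observation-level resampling) or more replicates.

## Chemical space

Compounds are bit sets (substructure fingerprints); similarity is the
Tanimoto/Jaccard index, defined as 0 when both sets are empty. Library
coverage is each query's maximum similarity over the library (ties broken
by sorted library id); coverage distributions are compared with the
two-sample Kolmogorov–Smirnov test using the asymptotic p-value (intended
sample sizes are hundreds or more; exact small-sample p is out of scope).
The RDKit adapter produces Morgan/ECFP fingerprints at radius 2, 2048
bits (recorded defaults); all set arithmetic is independent of the
chemistry backend.

## Activity classification

Per species, a random forest (500 trees, √p features per split, unlimited
depth) predicts inhibition probabilities. "20× cross-validation" is
implemented as 20 independent stratified 8:2 shuffle-splits — repeated
splits, not a 20-fold partition — with the positive-class frequency
preserved in train and test. Classification thresholds the probability at
the training split's hit frequency (≥, so a probability exactly at the
prevalence is called positive), the standard remedy for heavily
imbalanced screens where the 0.5 threshold collapses sensitivity.
Balanced accuracy is (sensitivity + specificity)/2; average precision is
the stepwise area under the precision–recall curve with tied scores
processed as one block. Shuffled-label refits of the identical pipeline
provide the chance-level null for both metrics. A descriptor-only mode
restricts training to the descriptor feature block, excluding the learned
embedding columns.

## Community and bioaccumulation arithmetic

Relative abundances are count proportions; the absolute-abundance proxy
scales them by culture OD, so treated/control ratios are invariant to
sequencing depth and linear in biomass. Calibration-curve quantification
fits an ordinary least-squares line from standards and inverts it, with
out-of-range samples flagged as extrapolated. Percent depletion is
100·(1 − mean supernatant / mean whole culture) with a two-sided Welch
t-test on the replicate concentrations.

## Synthetic data: what it emulates and what it does not

The generators mirror the screening study's structure: 96-well plates
with eight interspersed DMSO wells and one dye-footprint well, hourly
OD600 reads for 24 h from a starting OD of 0.05, three biological
replicates, 20 µM single-dose treatment, 5% multiplicative lognormal
well noise, planted inhibitory interactions at 50–95% AUC reduction.
Inhibition is planted by shrinking the above-inoculum part of the
logistic curve by the effect size — equivalent to scaling the carrying
capacity toward the inoculum — so the noiseless normalized AUC equals
exactly 1 − effect and recovery can be scored without tolerance
ambiguity. Dose–response series use a Hill curve whose value crosses the
0.1 MIC threshold exactly at the planted MIC on two-fold dilution grids.
Arrayed libraries emulate 185 mutants over two runs × two technical
plates. Insertion counts are negative binomial (dispersion 0.2) around
lognormal site weights with per-sample depth factors, sites placed
uniformly within 900-bp genes. Compound libraries are independent
Bernoulli fingerprint bits with a planted conjunctive structure–activity
rule (active iff all rule bits set; rule-bit density prevalence^(1/k)
fixes the label prevalence) plus a 768-column noisy linear projection of
the bits standing in for a learned embedding. Communities are
Dirichlet-lognormal compositions with multinomial reads and planted
per-species sensitivity scalars.

None of this reproduces real data's structure beyond those features:
no well-position autocorrelation, no compound carry-over, no phylogenetic
correlation between strains, no linkage between fingerprint bits, no
chimeric reads. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under its stated model — not that the
thresholds are optimal for any particular laboratory's noise regime.

## Problem sizes used in the validation runs

Null hit-calling uses 12 plates (1,044 compounds) × 3 replicates; planted
recovery uses 1,000 compounds × 8 strains at 10% planted hits; MIC
exactness uses 100 pairs on an 8-point two-fold grid; permutation-oracle
agreement uses 50 genes in a 2-vs-3 design; null calibration and planted
recovery for the transposon screen use 2,000 genes at 8 + 8 samples (see
above); the arrayed screen uses 185 mutants with detection probability
estimated over 40 simulated screens; the classifier runs 800 compounds at
prevalence 0.15 with 20 splits and a 20-shuffle null, in descriptor-only
mode — with the embedding block included, the conjunction rule's forest
probabilities spread enough that prevalence thresholding costs roughly
0.1 of balanced accuracy while average precision stays near 1, which is
why the descriptor-only configuration is the reference one. These sizes
are the package's reference designs; all are configurable.
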