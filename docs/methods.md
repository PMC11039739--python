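# Methods

This note records the models implemented by `crisprmod`, their assumptions,
the defaults and why, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Screen model and hit calling

Guide counts are modelled as negative binomial with mean μ and variance
μ + αμ², the standard overdispersed model for pooled-screen sequencing
counts; α is the `dispersion` parameter (default 0.1, a typical value for
replicate screens at moderate depth). Library representation is uneven in
real screens, so per-guide abundances are drawn log-normal with σ = 0.5 and
normalized to mean 1; this skew is what makes depth normalization
non-trivial and is deliberately exercised by the tests. Selection is
multiplicative: in drug-treated samples the expected abundance of every
guide of a resistance gene is multiplied by `resistance_effect`. The default
screen has 1,000 genes × 3 guides, 20 resistance genes with effect 4,
mean depth 500 reads/guide, and duplicate replicates of four drug
conditions (two drugs × two doses) plus a vehicle arm — a deliberately
scaled-down version of a genome-wide screen that one CPU can simulate and
analyse in seconds. The real effect sizes of true screen hits are unknown;
effect 4 is a calibration choice, not an estimate, so recovery statistics
quantify the pipeline's behaviour at these conditions only.

Normalization defaults to median-of-ratios against the geometric-mean
pseudo-reference over guides detected in every sample, because it is robust
to the composition shift a strong selection arm induces (a few hugely
enriched guides inflate totals and would bias total-count scaling). Size
factors are centred to geometric mean 1, which makes normalization
idempotent. Total-count normalization is available as the simple
alternative.

Fold differences compare replicate means of drug versus vehicle with a
pseudocount (default 1) guarding zero vehicle means; day-0 samples can be
generated but are never used by the caller, which compares against vehicle.
The threshold comparison is strict (FD > 1.8), "multiple guides" is
interpreted as ≥ 2 of the 3 library guides (configurable), and the
cross-screen rule requires enrichment under every drug at one or more of
its doses. Ties at exactly the threshold therefore do not count. The number
of k-means clusters is user-set (default 4, one per drug × dose condition);
k-means uses k-means++ initialization with a fixed seed and 10 restarts.

Null calibration: with effect 1.0 the expected gene-level false-call rate
per screen is derived from the empirical per-guide tail mass
q = P(FD > τ) as 3q²(1−q) + q³ (≥ 2 of 3 independent guides passing),
and the observed number of enriched genes is checked against the central
95% binomial interval. This treats guides as independent given the
simulation, which holds because abundances and counts are drawn per guide.

## Expression, GSEA and ΔΔCt

Quantile normalization maps each sample's sorted values onto the
cross-sample mean of sorted values, with average-rank handling of ties
(tied values receive the mean of the reference values their rank span
covers). It is exactly idempotent on tie-free data; with ties the averaging
convention re-blends reference values, so idempotence is only approximate
— ties are measure-zero for continuous expression values.

Differential expression is deliberately simple — per-gene group means,
treated/control ratio and percent change — because the downstream triage
consumes magnitudes, not p-values. A gene is "altered" when
|percent change| strictly exceeds a threshold whose default, 20%, matches
the validation stage's criterion; genes with a zero control mean have no
defined ratio and are excluded from rankings with a reported count.

The GSEA engine implements the weighted running-sum enrichment score: hit
increments |score|^p normalized by their sum, miss decrements 1/(N − N_h),
ES = the maximum deviation from zero. The default weight p = 1 is the
classic weighted statistic. Significance uses **gene-set permutation**
(random same-size sets drawn from the ranked list) rather than phenotype
permutation, because the motivating designs have ~3 replicates per arm —
far too few phenotype labels to permute. NES divides ES by the mean of
same-sign permutation scores; the nominal p is the same-sign tail fraction
with the usual +1 correction. 1,000 permutations by default, all seeded.
FDR q-values and leading-edge analysis are out of scope. Numerically, the
running-sum extremes are computed from hit positions alone (O(k) per
evaluation), which is what makes thousands of permutations cheap; when the
positive and negative extremes nearly cancel (|sum| < 1e−9) the instance is
re-evaluated in exact rational arithmetic so the reported sign is the true
first-attained extreme rather than an accumulation-order artefact.

ΔΔCt: per sample, ΔCt = Ct_target − Ct_reference; ΔΔCt is the difference of
group means; fold = 2^(−ΔΔCt). Any plate-wide Ct offset on a sample cancels
in ΔCt, which the tests assert.

## Target triage

The funnel joins four evidence layers with the boundary semantics printed
in its sources: the prediction cutoff is inclusive (score ≤ −0.01, more
negative = stronger predicted repression), downregulation is strict
(> 20%). The microarray-stage downregulation threshold is not separately
specified anywhere authoritative, so it defaults to the same 20% magnitude
as the validation stage and is configurable. Prediction tables and pathway
maps are always *inputs* (TSV), never fetched: upstream database versions
are irreproducible, and the synthetic prediction generator plants truth
instead. Which pathways count as "cancer-associated" is a user decision
supplied as the designated-pathway set.

## Dose-response and Loewe synergy

The dose-response model is the four-parameter logistic
f(d) = bottom + (top − bottom)/(1 + (d/ED50)^hill), the standard viability
model behind common curve-fitting workflows; the fit is multi-start
least squares (5 × 4 grid of ED50/Hill starts, bounded, best residual wins)
on replicate-averaged viability, with an honest convergence flag. A
response with dynamic range under 0.05 is flagged non-determined rather
than fitted. ED50 is definitional: the fitted curve evaluated at the
returned ED50 equals (top + bottom)/2.

Loewe additivity: the expected combination response solves
d_A/D_A(y) + d_B/D_B(y) = 1, where D(y) inverts the 4PL curve. The left
side is monotone in y, so the root is unique and found by bracketed Brent
iteration to 1e−10; inverse evaluation clamps y to (bottom + ε, top − ε)
with ε = 1e−6 of the span to keep doses finite. The sham-combination axiom
(a drug combined with itself behaves as its summed dose) falls out of the
definition and is asserted in tests. Synergy scores are expressed in
viability percentage points (100 × expected fraction − observed percent),
positive = excess killing, averaged over cells where both doses are
positive, with the conventional > 10 / −10…10 / < −10 bands. SynergyFinder's
version-dependent baseline corrections and smoothing are *not* replicated;
the Loewe definition is implemented directly and the bands applied to it,
so exact numeric reproduction of any particular published grid is not a
goal.

The dose-matrix generator plants exact Loewe additivity plus a constant
interaction offset and Gaussian noise, clipping to [0, 110]%. Its default
monotherapies (top 1, bottom 0.2, ED50 100 and 50 nM, Hill 1.5 and 1.2) and
7 × 7 grids (0–1000 nM starting at 30 nM) are chosen so every combination
cell's additive expectation sits well inside the clip range: a matrix
measured against the asymptotes cannot encode a ±15-point offset, because
clipping destroys it. Offset-recovery statistics therefore measure the
scorer, not the clip.

## Survival

Expression is dichotomized either at a cohort-wide z-score (default
cutoff 1) or at a user-supplied absolute value; the absolute mode exists
because bimodal expression distributions are better split at a manually
chosen valley than at a z-score, and scanning many cutoffs for the minimal
p-value is deliberately not implemented (it inflates type I error).
The z-score is computed over the whole cohort, not per stratum.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
behind this module's interface; tests verify them against hand-tabulated
product-limit and observed-minus-expected/hypergeometric-variance oracles
on small cohorts. The median-survival convention is the smallest observed
event time with S(t) ≤ 0.5 (step-function reading); ties between events
and censorings at a time are resolved events-first.

The survival generator draws expression from a two-component Gaussian
mixture (default means 0 and 4, unit SDs, weight 0.5) and exponential event
times whose hazard (baseline 0.02 per unit time) is multiplied by
`hazard_ratio` for the high component. Censoring selects a Bernoulli
fraction of subjects and truncates their time uniformly on (0, T): this
delivers exactly the requested expected censored fraction but is not
administratively independent censoring — adequate for the calibration and
power experiments this module exists for, but not a model of any real
accrual process. Calibration experiments dichotomize at the mixture
midpoint, mirroring the manual-cutoff procedure.

## What the synthetic data does and does not show

The generators reproduce the *structure* of each input — overdispersed
counts with library skew, multiplicative selection, fixed-fraction target
knockdown with log-normal noise, exact Loewe surfaces, mixture-driven
hazards — but none of the messier features of real data: guide-efficiency
heterogeneity, off-target effects, batch and plate effects, probe-level
microarray artefacts, non-4PL monotherapies, or informative censoring.
Passing recovery tests therefore demonstrates the correctness and
calibration of the *algorithms* at the stated conditions, not expected
performance on any particular real screen.

## Problem sizes

Defaults throughout (1,000-gene screens, 2,000-gene expression matrices
with 50 targets, 7 × 7 dose grids, 200-patient cohorts, 1,000 random gene
sets × 200 permutations, 100–500 replicate experiments) were chosen as the
smallest sizes at which the recovery and calibration statistics are stable,
so the whole validation battery runs in about a minute on one CPU.
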