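# Methods

This note documents the models and procedures implemented in `iraps`, the
choices made where the design was genuinely open, and what the synthetic
data used by the test-suite does and does not establish about real data.

## Normalization

The preprocessing chain is log2 transform → quantile normalization →
per-tissue Tukey median polish.

* **log2**: `log2(x + offset)` with a default offset of 1 for raw
  intensities (configurable).  Nonpositive values under the chosen offset
  are a hard error with cell coordinates, not silently clipped.
* **Quantile normalization** forces every sample (column) onto the
  across-sample mean of order statistics.  Ties within a column receive the
  mean of the reference values at their tied ranks ("average ties").  Rank
  order within a column is always preserved.  On tie-free data the
  operation is exactly idempotent; tie-averaging couples columns, so in the
  presence of ties a second application can move tied groups by a small
  amount.  Single-sample matrices pass through unchanged with a warning.
* **Median polish** decomposes each tissue's block as
  `x[i,j] = overall + gene[i] + sample[j] + residual[i,j]` by alternating
  row/column median sweeps (default: at most 10 sweeps, stopping when the
  sum of absolute residuals changes by less than a relative 1e−6).  The
  reconstruction identity holds exactly at any iteration count, and both
  effect vectors are re-centered into the overall term on exit so their
  medians are exactly zero.
* **Per-tissue composition**: within each tissue, quantile normalization
  is followed by median polish, and the returned matrix keeps the sample
  effects plus residuals — i.e. the overall and gene effects are removed,
  centering every gene within its tissue.  This is the standard use of
  per-tissue polish in pan-cancer panels: cross-tissue baseline expression
  differences would otherwise dominate responder/non-responder contrasts.
  Tissue groups of size one pass through centered at zero.  Whether
  quantile normalization runs within tissue (default) or once across the
  panel is configurable.

## Responder classification

Sensitivity values are standardized per drug across the panel (sample
standard deviation, ddof = 1).  IC50 values are natural-log transformed
first (they are approximately log-normal across panels); dose-response AUC
values are standardized directly; both behaviors are configurable.  The
single-agent rule is: responder if z < −1, non-responder if z > 0, neither
otherwise — strict inequalities, so boundary values fall in the middle
band.  Under a standard normal z this labels ~16% responders and ~50%
non-responders.  The dual-inhibitor rule averages the two z-scores and
additionally requires each drug to reach ≤ −0.5 for a responder (the
boundary counts as satisfying the guard; the guard exists to exclude
lines that respond to only one of the two inhibitors) and both drugs
above 0 for a non-responder.

By default z-scores are computed once on the full candidate pool and
labels follow each subsample (classification precedes iteration, keeping
labels stable across resamples); re-standardizing within every subsample
is available behind a flag.

## Iterative resampling

Each iteration draws `floor(fraction · n)` cell lines (default fraction
0.5) uniformly without replacement from the pool of lines with both
expression and response data — held-out test ids are removed *before* any
sampling.  Per gene, a two-sided Welch unequal-variance t-test compares
responders and non-responders, with the log2 fold change defined as mean
log2 expression in responders minus non-responders.  Welch was chosen
because per-iteration group sizes are small and unequal (~15 vs ~50);
variance-moderated tests are deliberately out of scope.  Iterations whose
responder or non-responder group falls below `min_group_size` (default 5)
are skipped and counted, never padded.  Samples are canonically sorted
before the RNG is applied so archives do not depend on input file order;
the archive is bit-reproducible from the seed.

No per-gene multiple-testing correction is applied inside iterations: the
conservation filter in the grid search is the mechanism that controls
false discoveries.

## Grid search and the signature

At thresholds `(p_thr, fc_thr, cons_thr)` a gene's **conservation
fraction** is the fraction of retained iterations with `p < p_thr` and
`|log2FC| > log2(fc_thr)` *in the gene's majority direction*.  Fold-change
thresholds are ratios (1.25 means `|log2FC| > log2 1.25`).  The
majority-sign requirement (ties broken by the sign of the summed
qualifying fold change) exists because a signed weight is meaningless for
a gene that flips direction between resamples; it can be switched off.
The gene's weight is its mean log2 fold change over the sign-consistent
qualifying iterations — for a conserved gene this is nearly identical to
the mean over all iterations, and it cannot be diluted by iterations in
which the gene showed no effect.

The default grid is p ∈ {1e−2, 1e−3, 1e−4, 1e−5}, fold change ∈
{1.1, 1.25, 1.5, 2.0}, conservation ∈ {0.5, 0.6, 0.7, 0.8, 0.9, 0.95};
all three lists are configurable.  Candidates with fewer than `min_genes`
(default 5) genes are skipped to keep degenerate near-empty signatures
from winning by chance.  Each remaining candidate scores the training
samples (restricted to the target tissue(s)) and records the ROC AUC with
responder as the positive class, "neither" samples excluded.

**Selection and tie-breaking.**  The candidate with the largest training
AUC wins.  Exact AUC ties are common whenever the training panel is
cleanly separable — many threshold combinations then saturate — so the tie
order matters: ties go first to the largest conservation threshold (a
stricter stability requirement at equal accuracy), then to the candidate
with the *most* genes (at equal accuracy, discarding qualifying genes
throws away redundancy that helps a signature transfer to cohorts profiled
on other platforms or with missing genes), then to the smaller p
threshold.  An optimizer that cannot find any usable candidate — or whose
best candidate is worse than chance — raises an error carrying the full
grid table rather than returning a signature.

## Signature scoring and evaluation

A sample's score is the Pearson correlation between the signature weights
and the sample's expression over the signature genes, after centering each
gene at its cohort median.  Centering is the single largest interpretive
choice in scoring: without it, absolute expression level rather than
relative deviation dominates the correlation.  Raw-scale scoring and
Spearman correlation are available by flag.  Signature genes absent from
the matrix are dropped symmetrically (reported in the result); fewer than
`min_overlap` (default 3) common genes is an error.

Evaluation sweeps score thresholds (tie groups collapsed) to build the ROC
curve and integrates it by the trapezoid rule; this equals the
Mann–Whitney U identity `U/(n⁺·n⁻)` including ties, which the test-suite
verifies against an independent implementation.  The accuracy threshold
defaults to the Youden point (max TPR − FPR) on the data being evaluated;
for honest test-set accuracy, freeze the training Youden point and pass it
as a fixed threshold.

The stratified drug screen splits samples at score > mean + 1 SD (high)
vs score < mean (low), drops drugs whose mean response-AUC in the high
stratum exceeds a toxicity cutoff (default 10 — the response-AUC scale is
dataset-specific, so the cutoff is configurable), and ranks the survivors
by a two-sided Welch test of sensitivity values high vs low.  A negative
effect (mean high − mean low) means the high-scoring stratum is more
sensitive.

## Survival

The two-group log-rank statistic is computed from the standard
observed-minus-expected table with the hypergeometric variance;
simultaneous events at a time all count within that time's risk set.  The
optimal cutpoint scans every midpoint between consecutive distinct scores
whose split leaves at least `min_group_frac` (default 0.2) of the patients
on each side, and returns the split maximizing the statistic.  Because the
cutpoint is optimized, the p-value at the chosen split is anti-conservative;
the result carries an explicit `p_value_is_optimistic` flag and no
correction is applied.  Cox proportional-hazards fits (for hazard ratios
adjusted by stage/grade-type covariates) are delegated to lifelines —
plumbing, not re-derived math.

## Synergy

The median-effect equation `fa/fu = (D/Dm)^m` is fitted by ordinary least
squares on `log(fa/fu)` vs `log D` (slope m, intercept −m·log Dm).
Fractions affected at the assay floor/ceiling are clamped into
(0.005, 0.995) with a warning; the clamp width is configurable.  At least
three usable dose points are required.  The combination index at effect
level fa uses the two-term mutually exclusive form by default (the common
CompuSyn-style default); the mutually nonexclusive variant, which adds the
product term, is available by flag.  At fa = 0.5 the CI reduces exactly to
`d_A/Dm_A + d_B/Dm_B`.  Isobologram coordinates (axis intercepts and the
combination point) are emitted for plotting; the combination point lies
below the additivity line exactly when CI < 1.

## Synthetic data: what it emulates, and what it does not

The panel generator plants the coupling the method assumes: one latent
sensitivity factor `s ~ N(0,1)` per cell line drives both a subset of
genes (`expression = baseline + sign·effect·s + N(0,1)`, effect in log2
units per SD of s) and the drug responses
(`z_k = sqrt(ρ)·s + sqrt(1−ρ)·ε_k`, so the two drugs' z-scores correlate
ρ and each correlates `sqrt(ρ)` with the factor; IC50-like values are
`exp(z)`).  Because responders are the *low*-z (low-IC50) lines, a gene
coupled positively to s is under-expressed in responders: its expected
signature weight is the negative of its coupling sign, and the ground
truth object records both.  The construction requires ρ ∈ [0, 1]; ρ = 1
makes the two drugs identical.

Defaults — 2,000 genes × 200 lines, 60 planted genes, effect 1.2, ρ = 0.8,
two tissues assigned round-robin — are the study conditions used by the
test-suite: large enough to exercise the full grid search, small enough to
run in well under a minute.  Under these conditions the pipeline typically
recovers all planted genes with correctly signed weights and near-perfect
held-out AUC; when the training panel saturates unevenly across grid
points, AUC granularity can occasionally restrict the max-AUC tie set to
stricter thresholds and reduce completeness (precision stays at 100%).

The generator does **not** emulate real panel covariance structure, batch
or platform effects, tissue-specific biology, mutation data, or
heavy-tailed response distributions.  Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms under the
model's own assumptions — not clinical performance on real cohorts.

The survival generator draws scores from N(0,1) and exponential event
times with rate `base · hr^score` (or a single hazard step at a planted
cutoff), then censors each record with the requested probability at a
uniform fraction of its event time.  The dose-response generator inverts
the median-effect equation with optional Gaussian noise, clamped inside
(0, 1).

## Numerical choices and degenerate inputs

* Welch p-values of exactly constant, identical groups are defined as 1
  (t = 0/0); separated constant groups take the smallest positive float.
  p-values are clipped into (0, 1].
* Zero-variance samples in scoring receive score 0 with a logged warning;
  scores are clipped into [−1, 1] against floating-point overshoot.
* Zero-variance sensitivity vectors, all-censored survival groups,
  single-class evaluation inputs, and flat dose-response series are hard
  errors, not silent results.
* Duplicate gene ids are collapsed by their mean on read (deterministic
  and symmetric), with a warning.

## Problem sizes used by the test-suite

End-to-end tests run the default 2,000 × 200 panel with 200 resampling
iterations and a 100-sample held-out cohort; unit tests use panels down to
tens of genes.  Null-uniformity checks pool p-values across three panels
(6,000 gene-level tests) for a stable empirical CDF; Cox coverage uses 50
cohorts of 200 patients.  The full suite completes in about a minute on a
single CPU.

## Known limitations

* The optimal-cutpoint p-value is reported unadjusted (flagged); use it
  for ranking splits, not as a calibrated significance level.
* Conservation counting treats iterations as exchangeable; it does not
  model the strong dependence between overlapping half-samples.
* The screen's toxicity cutoff and the IC50 log-transform convention are
  dataset conventions, not inferred from data.
* GCT support is read-only (version 1.2); TSV is the canonical format.
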