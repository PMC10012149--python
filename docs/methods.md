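# Methods

`ppmet` analyses a three-arm postprandial crossover: each participant drinks a
water control (WC), a 12.5 g (LP) and a 50 g (HP) whey-protein-isolate
beverage on separate visits, with plasma sampled fasted (T = 0) and at 30, 60,
120 and 240 min. The pipeline isolates metabolomic features with a genuine
dose-by-time response, models which of them discriminate participant classes,
and interprets the resulting panel through network topology and pathway
over-representation. Everything is exercised against a synthetic cohort
generator with planted ground truth, so the statistical behaviour of every
stage is measurable.

## Synthetic cohort generator

The generator emulates the study design rather than instrument physics: 24
female participants split 12/12 by an ethnicity-like binary class, a 20-member
subset split 10/10 by a pancreas-fat-like label, 3 meals x 5 timepoints per
participant (360 nominal samples), and a few hundred features.

Feature intensities are log-normal around a per-feature baseline
(log-mean 11, log-SD 1 — typical Orbitrap peak-area magnitudes). A
*responsive* feature adds, on the log scale, a gamma-like rise-fall excursion
`c(t) = (t/tp)^s · exp(s·(1 − t/tp))` (peak time `tp` = 60 min, sharpness
`s` = 2; zero at T = 0, unit peak) scaled by a per-meal amplitude. Default
amplitudes are (0.1, 0.4, 0.8) for WC < LP < HP. The water control keeps a
small nonzero excursion deliberately: a drink of any kind perturbs the
postprandial metabolome slightly, and a strictly zero control response would
make incremental-AUC ratios against the control degenerate. *Discriminative*
features multiply their amplitude by `1 + class_effect_size` for the second
class. Nuisance structure: participant random intercepts (log-SD 0.25),
i.i.d. log-scale noise (SD 0.15), multiplicative linear injection-order drift
shared by samples and pooled-QC injections, 2 batches x 10 QC injections, and
sporadic whole-row missingness (rate 0.006 ≈ 2 of 360 rows — whole samples
fail, not single cells). What the generator does **not** emulate:
chromatographic peak shapes, adducts/isotopes, heteroscedastic
intensity-dependent noise, or correlated feature blocks. Passing tests
therefore demonstrate the statistical machinery under the designed covariance
structure, not robustness to every artefact of real LC-MS data.

## Preprocessing

Order is fixed: KNN imputation → LOESS drift correction → QC-CV filter →
normalization.

- **KNN imputation** (k = 5): a row with missing cells is completed from the
  k nearest fully-observed rows (Euclidean distance over the features the
  query row observes), taking the neighbour mean. Complete rows pass through
  untouched.
- **Drift correction** is ratio-based QC-RLSC: per feature and batch, a
  locally weighted regression (span 0.75) of pooled-QC intensity on injection
  order; every intensity is divided by the fit interpolated at its injection
  position and re-anchored to the batch QC median. Flat QC series reproduce
  the input to 1e-9.
- **QC-CV filter**: features undetected (missing/zero) in any QC injection,
  or with QC CV = sd/mean ≥ 0.30 (sample SD, n−1), are removed with a
  reasoned report.
- **Normalization**: features failing Shapiro-Wilk at p ≤ 0.05 are
  natural-log transformed first. If a feature contains non-positive values it
  is shifted so its minimum sits half its smallest positive value above zero
  before the log — rank-preserving and never NaN (a pure additive offset of
  half the smallest positive value cannot rescue strongly negative values, so
  the shift variant is used). All features are then mean-centred and scaled:
  unit-variance (default), Pareto (÷√SD) or level (÷mean).

QC rows are dropped after the CV filter; normalization and all downstream
statistics see study samples only.

## Temporal screen

Per feature, a linear mixed model
`intensity ~ Meal + Time + Meal:Time + Age + BMI + (1 | participant)` is fit
by maximum likelihood; Meal (3 levels) and Time (5 levels) are categorical,
so the interaction block carries 8 degrees of freedom. The screen statistic
is the likelihood-ratio `2(ℓ_full − ℓ_no-interaction)`; ML rather than REML
because the compared models differ in fixed effects.

The fitter exploits the single-random-intercept structure: with
`θ = σ_b²/σ²`, both β and σ² profile out, leaving a 1-D likelihood evaluated
from per-group sufficient statistics in O(G·p²) per evaluation, independent
of n. It matches a general-purpose mixed-model ML fit to ~1e-8 on fixtures
and is ~100x faster — which is what makes a 10,000-permutation screen
tractable. A relative floor on the profiled residual sum of squares
(`n · var(y) · 1e-12`) handles exact-fit degeneracies (zero-noise
simulations) by sending both nested fits to the same floor, so degenerate
features score a zero statistic instead of numerical garbage.

Significance is by permutation: under the null of no meal effect a
participant's three visit curves are exchangeable, so meal labels are
permuted across whole visits within each participant. This preserves
within-visit autocorrelation and each participant's age/BMI. The add-one
estimator `p = (1 + #{perm ≥ obs})/(B + 1)` never returns zero. The same B
relabelings are shared across all features, which lets the per-permutation
design factorization be computed once per permutation and keeps feature
p-values comparable. Benjamini-Hochberg q-values are computed across
features; features with q ≥ 0.05 are filtered out (strict `q < threshold`
retained).

**Permutation granularity.** The estimator's floor is `1/(B+1)`. With m
features of which n_true are truly responsive, a saturated block of true
positives reaches q ≈ m/((B+1)·n_true); retaining them at threshold q* needs
roughly `B ≥ m/(q*·n_true)`. At B = 199, m = 100, n_true = 10 the planted
block lands exactly on q = 0.05 and is filtered by the strict rule — an
arithmetic tie, not a power failure. Calibration runs therefore use B = 399
for recall measurements (type-I calibration keeps B = 199, where the floor
is irrelevant).

## Incremental AUC and the fold-change gate

The baseline of a participant x feature is the participant's mean fasted
(T = 0) intensity across their visits — a per-participant constant. (The
alternative pooled-across-participants reading is not implemented; the
per-participant reading respects the crossover pairing.) A *peak* is a
maximal run of consecutive points strictly above baseline; it is kept iff it
spans ≥ 3 adjacent timepoints and its apex reaches ≥ 75% of the series'
min-to-max range. Net area = trapezoidal area above baseline contributed by
kept peaks (including the flanking segments that connect a kept run to the
baseline) minus the whole series' area below baseline; baseline-crossing
segments are split at the interpolated crossing, making areas exact for
piecewise-linear series. With the filters disabled this reduces exactly to
the plain net trapezoid, which is the test oracle.

Per feature, log2 fold changes compare mean net areas across participants:
LP/WC and HP/WC. "Significant" fold change is `|log2FC| ≥ 1` (two-fold),
configurable — a conventional default, since no test or threshold is
otherwise determined. If either group mean is non-positive the ratio is
undefined: the feature is flagged sign-indeterminate and set non-significant
rather than patched with a pseudo-count. The gate then keeps features
significant in both comparisons or in HP/WC alone, and removes features
significant in LP/WC alone (non-dose-consistent responses are treated as
screen false positives).

## SVM-RFE with nested cross-validation

Participant-level design matrix: one row per participant, columns the
shortlisted features, value `net iAUC(HP) − net iAUC(WC)` — the
participant's dose response relative to their own control (a "stacked meals"
mode keeps LP and HP columns separately). Columns are standardized.

Within each of 10 stratified outer training folds, recursive feature
elimination scores surviving features by the squared weights of a linear SVM
(C = 1, untuned — only the RBF stage is tuned) and removes the weaker half
per round while more than `halving_floor` = 50 features survive, then one
per round. Rank 1 is the last survivor; ranks are averaged across folds
(smaller = stronger contribution). Outer folds are stratified and seeded
because unstratified 10-fold on n = 24 can produce single-class folds.

Generalized error for a top-N panel: in each outer fold, the top-N features
are taken from **that fold's own training ranking**, an RBF SVM is tuned
over a cost x gamma grid by inner stratified CV on the training fold only,
refit, and scored on the held-out fold; the curve is the mean held-out
misclassification over folds. Selecting from the fold-averaged ranking
instead would leak feature selection (every sample informs 9 of the 10
training rankings); measured on permuted labels that variant scores ~0.17
instead of chance, so it is supported only for reporting a fixed panel, not
used for error estimation. The optimal N is the smallest with error strictly
below 0.05; when no N qualifies the model reports none — which is exactly
the expected behaviour of the dummy (label-randomized) negative controls.
Dummy labels come as a single class-preserving permutation (default; a
well-defined control classification problem) or as independent per-column
random reassignments (the literal per-feature-column shuffle; a data product
only, since it defines no single classification problem). Error is plain
misclassification (accuracy complement); with balanced classes it equals
balanced error.

Default grids are cost ∈ 2^[−5…15], gamma ∈ 2^[−15…3], 8 log-spaced points
each, with 10 inner folds. Repeated-seed property runs use a reduced budget
(3x3 grid, 5 inner folds, 6 panel sizes) — the error landscape of an RBF SVM
on n ≈ 20 is coarse enough that the reduced grid identifies the same
operating regime.

## Multivariate validation

PCA (SVD on the centred panel) reports per-component explained variance
against an eigendecomposition oracle. PLS-DA regresses the centred 0/1 class
indicator on the standardized panel with a NIPALS latent-variable fit, two
components by default (matching 2-D score-plot practice); R2X/R2Y are
cumulative explained fractions. Q2 = 1 − PRESS/TSS accumulated over
stratified held-out folds (k = 7, a common PLS default), with
standardization statistics from the training folds only. Permutation
validation refits under 100 random label permutations ("100-fold
permutations" read as 100 label permutations, the permutation-plot
convention); the model is *valid* iff the unpermuted Q2 exceeds every
permuted Q2 — chosen because no numeric criterion is otherwise defined.
These are structural analogues of commercial-software output, not numeric
reproductions: component count, scaling and Q2 conventions differ between
implementations.

## Network topology and pathway enrichment

The knowledge base is an input: a typed edge list
(compound/reaction/enzyme/gene) in SIF or CSV form. The build keeps every
connected component touched by at least one query compound; query compounds
absent from the base are dropped with a warning (annotation is never
complete), present ones are flagged `input_compound`. Relative betweenness
centrality is the fraction of all-pairs shortest paths through a node with
fractional credit for ties, normalized by (n−1)(n−2)/2 **within each
connected component** so values lie in [0, 1] even for multi-component
networks. Hubs require degree and betweenness above thresholds (defaults 10
and 0.1); the comparison is inclusive (≥) by default with strict (>)
available, because published hub tables occasionally include the boundary.

Over-representation: upper-tail hypergeometric `P(X ≥ hits)` with population
= the universe (default: union of all library compounds), successes = the
pathway size, draws = |query ∩ universe|. Adjustment is Holm-Bonferroni by
default with Benjamini-Hochberg available. Pathway impact is the share of a
pathway graph's betweenness importance carried by the hit compounds (summed
importance, not maximum — the summed form makes impact a coverage fraction
in [0, 1]); when every node has zero betweenness (cliques), importance is
spread uniformly so full coverage still scores 1. The bundled 80-pathway
library and compound/reaction/enzyme/gene base are synthetic stand-ins
generated programmatically at the backend's scale; real databases are passed
in as files.

## Pipeline and reproducibility

Stages (simulate → preprocess → screen → gate → rank → validate → network →
enrich) read and write a run directory, so any stage re-runs bit-identically
from persisted intermediates. The manifest records the config echo, a
deterministic per-stage seed derived from the global seed, and the SHA-256
of every output file; two runs with the same config differ only in the
timestamp. The CLI (`ppmet`) exposes one subcommand per stage plus
`run-all`; exit codes are 0/1/2 for success/user error/internal error. The
multivariate stage validates the ranked top panel (top 20 by default) with
the component count clamped to the panel size.

## Problem sizes used by the test suite and acceptance runs

Library defaults stay at the full study values (B = 10,000 permutations,
8x8 tuning grids, full top-N sweep). The repeated-seed property runs use:
type-I calibration at 200 null features / B = 199; recall at 100 features
(10 responsive, amplitudes (0, 0.25, 0.5) against noise SD 0.15, i.e. a
peak excursion ≥ 3 noise SDs) / B = 399; ranking recovery and dummy curves
over 20 seeds with the reduced tuning budget; end-to-end runs at 40-60
features / B = 199. These sizes are the package's own choices for
repeated-measurement studies of its behaviour.

## Known limitations

- Ranking recovery at the boundary planted effect (1.5 SD, n = 24, 100
  features) is information-limited: even univariate oracle ranking places
  all 5 planted markers in the top 10 in only ~85% of seeds, and SVM-RFE
  (any variant measured: single-fit, one-by-one, stability-scored) reaches
  ~50%. The recovery rate is reported as measured.
- The mixed model supports a single random intercept only — no random
  slopes or autoregressive residuals, by design.
- The generator's feature independence means multiplicity behaviour under
  correlated features is not exercised.
- SIMCA-style software parity for PLS-DA quantities is out of scope.
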