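# Methods

## The analysis problem

A humanized-mouse immunization study yields, per animal, gated
flow-cytometry summaries in up to six tissues: the human-CD45+ engraftment
level, the lineage composition within huCD45 (CD19 B cells, CD3 T cells,
CD14 monocytes — CD34 progenitors in bone marrow — and an "other"
remainder), the CD4/CD8 split of the T-cell compartment, the
naive/central-memory/effector-memory/terminal-effector (N/CM/EM/TE)
composition within CD4 and within CD8, and, for the thymus, the
DN/DP/CD4SP/CD8SP developmental composition, the TCRαβ+ fraction of CD3
and the CD4:CD8 single-positive ratio.  Frequencies are compositional
(blocks close to 100%); lymphatic tissues additionally carry absolute
counts.  The package quantifies how predictive these profiles are of
immunization status and which markers structure the between-group
difference.

## Synthetic cohorts

Real cohorts of this kind are small and rarely deposited, so the generator
is a first-class module.  Per mouse × available tissue it draws:

* engraftment huCD45% from a beta distribution (per-tissue mean and
  concentration);
* the four-part lineage composition from a Dirichlet, closed to exactly
  100%; "other CD45+" is always the remainder, never drawn independently;
* the CD4 fraction of CD3 from a beta (so CD4 + CD8 = CD3 by
  construction); N/CM/EM/TE compositions within CD4 and CD8 from
  Dirichlets;
* for THY, a DN/DP/CD4SP/CD8SP Dirichlet; CD3% is reconstructed as the
  single-positives plus a large fraction of DP (thymocyte CD3 expression
  rises through development); the CD4:CD8 ratio is derived as CD4SP/CD8SP
  at panel-building time rather than stored;
* a total human-cell count from a negative binomial with mean μ and
  dispersion k (variance μ + μ²/k, matching the NB2 regression family);
  every gated count is round(frequency/100 × parent count), so counts and
  frequencies are consistent by construction.  Blood is frequency-only.
  Thymus counts are absolute cell numbers (the convention is ambiguous in
  practice; this is the documented assumption).

Immunization effects are additive shifts δ on the log of the targeted
Dirichlet concentration, α′ = α·exp(δ), which moves the expected
composition log-odds by ≈δ and is analytically checkable via
E[p] = α′/Σα′.  A per-tissue sex modifier multiplies δ for females.
Default conditions: 11 control vs 17 immunized mice, balanced sexes,
per-tissue availability chosen so expected per-tissue sample counts match
the reference design (thymus 27/28, PLN+MLN 19/28, MLN 21/28, others
complete), and CD8 EM/TE log-odds raised in spleen and lymph nodes
(+0.9/+0.6, sex modifier 1.6; weaker in MLN and PB).  Effect magnitudes
are qualitative choices — directionally realistic, not calibrated to any
real dataset; only directions and the affected tissues are meaningful.
Dirichlet concentration totals of ≈40–60 give the 10–30% coefficients of
variation typical of gated frequencies between littermates.

What the generator does **not** emulate: cytometer artifacts (spillover,
gating error), litter/cord-blood-unit random effects on means (cb_unit is
recorded but exchangeable), longitudinal structure, and realistic
inter-marker correlation beyond what the compositional hierarchy induces.
Passing tests therefore demonstrate correctness of the estimators and
detection machinery on known ground truth, not expected performance on any
particular real cohort.

## Feature panels

`ann_markers`: 15 frequency markers per non-thymic tissue (huCD45, four
lineages, CD4, CD8, eight memory subsets), 8 for thymus.
`pca_variables`: percentages and counts jointly for BM and SPL (30),
percentages only for PB/PLN_MLN/MLN (15), and for THY the 8 marker values
plus the 6 compartment counts (14): the TCRαβ fraction and the CD4:CD8
ratio are derived quantities and have no meaningful absolute-count twin,
which reconciles 8 markers with 14 PCA variables.  Mice missing any panel
variable in a tissue are dropped with a logged warning (listwise, per
tissue).  Standardization is z-scoring with the sample (n−1) SD, computed
on the full per-tissue dataset by default — faithful to the emulated
workflow even though it leaks means across the later train/test split; the
ensemble can be run on matrices standardized any other way if stricter
hygiene is wanted.

## Ensemble classifier

One hidden layer of logistic-sigmoid units (12; 8 for THY — sizes
selectable by k-fold cross-validation over k ∈ {3,4,5}), two sigmoid
outputs, MSE against one-hot targets.  Levenberg–Marquardt suits this
scale: the full residual Jacobian (≈40 × 218 for a 20-sample tissue) is
cheap, and the damped normal-equations step interpolates between
Gauss–Newton and gradient descent.  Numerical choices: λ₀ = 1e−3, ×10 on
rejection, ×0.1 on acceptance, λmax = 1e10; max 100 epochs; gradient
tolerance 1e−7; early stopping after 6 consecutive validation-MSE
increases, returning the best-validation weights.  Initialization is
scaled-uniform U[−0.5, 0.5]/√fan-in; classification ties (both outputs
equal) go to control, a deterministic choice conservative toward the null.

Splits are unstratified 70/15/15 with test = validation =
max(1, ⌊0.15n⌋) — for the 28-mouse cohort: 20/4/4 — so with four test
samples a replicate occasionally scores a single-class test set;
sensitivity or specificity is then undefined for that replicate and is
excluded from that metric's mean, with the exclusion count reported.
Reported metrics are computed on the test partition only (an all-samples
scoring mode exists for sensitivity analysis).  All replicate seeds derive
from one master seed via `SeedSequence` spawning, making reports
bit-reproducible.

## PCA signatures

PCA is the SVD of the standardized group matrix with sample (n−1)
normalization; component signs are fixed so each component's
largest-magnitude loading is positive.  With 30 variables and ≈11 mice per
group the decomposition is necessarily rank-deficient; components beyond
n−1 carry zero eigenvalue, are dropped, and a warning is raised.  The
selection rule is strict |Pearson r| > 0.8 between a variable and a
component score (on standardized data this equals loading·√eigenvalue);
the first four components are checked against the conventional >80%
cumulative-variance criterion with a warning when unmet.  The "governing"
component is PC1 of the *control* group; its selected markers are the ones
whose pairwise correlations are compared across groups.

Signature classes use two configurable bands — neutral < 0.2 and
strong ≥ 0.5 in |r| — chosen so that near-zero correlations read as
neutral, mid-strength ones as weak, and ≥0.5 as clearly present:
*inverted* (sign flip, both |r| ≥ 0.2), *lost* (≥0.5 in control, <0.2 in
immunized), *gained* (mirror), *neutral* (both <0.2), *retained*
(everything else, including pairs that merely weakened).  The
classification is antisymmetric under swapping groups (lost ↔ gained).

## Group regressions

Frequencies: beta regression, logit(μ) = β₀ + β₁·group with constant
log-parameterized precision φ; exp(β₁) is the odds ratio.  Percentages are
first compressed off the boundary by y′ = (y/100·(n−1)+0.5)/n, since 0%
and 100% cells have zero beta likelihood.  Counts: NB2 negative binomial,
log(μ) = β₀ + β₁·group, joint ML over (β, log k); exp(β₁) is the rate
ratio.  Both likelihoods are maximized by L-BFGS with analytic gradients
followed by Newton polishing on the gradient norm, which makes
label-swap symmetry (effect → 1/effect, p unchanged) hold to ≈1e−12.
Standard errors come from the observed information (central finite
differences of the analytic gradient at the optimum); inference is
two-sided Wald z at 0.05 and 0.01.  For a single two-level factor the
model-implied group means on the link scale coincide with least-squares
means, so no separate LS-means machinery is needed.  No multiple-testing
correction is applied by default (per-marker inference at fixed levels);
dispersion/precision is constant, not covariate-modelled; cord-blood unit
is recorded but not adjusted for.  Non-converged fits (judged by the final
gradient norm and a positive-definite information matrix) are flagged and
excluded from report tables.  The variance F-test reports
F = larger/smaller sample variance with df ordered to match and a doubled
upper-tail p.

## Problem sizes in the shipped checks

The test-suite and acceptance-script runs use R = 200 ensemble replicates
(reference analyses use 2000; at these cohort sizes the ensemble mean has
stabilized well before 200), 20-seed recovery runs for the regressions,
500–1000 null simulations for type-I calibration, and 50-run detection
rates for signature classes — sizes at which every Monte-Carlo bound
asserted is conservative.

## Known limitations

* The LM trainer is dense and single-threaded; it is intended for panels
  of ≤ ~30 inputs and cohorts of tens of mice, not larger problems.
* Beta regression assumes constant precision across groups; strong
  heteroskedasticity would bias the Wald test.
* With 4-sample test partitions, per-replicate sensitivity/specificity are
  coarse (quartiles of 0.25); only ensemble means are meaningful.
* Group-wise PCA on 11 × 30 matrices is rank-deficient by construction;
  selected-marker lists are stable but component scores beyond the first
  few are noise.
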