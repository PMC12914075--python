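# Methods

This note documents the statistical models implemented in `protmed`, the
assumptions behind them, the synthetic generator's stated world, and the
numerical/design choices that were genuinely open.

## 1. Data conventions

Wide trial tables carry one row per subject with columns
`<variable>__<visit>` (visits `baseline`, `v1`, `v2`; default times 0, 1
and 9 months). Protein abundances are NPX values (log2 relative
quantification), so a one-unit NPX difference doubles abundance and the
protein fold-change is `2**(final − baseline)`. Concentrations (the
outcome biomarker, clinical measures) use the ratio `final/baseline`.
When the final visit is absent from a file, the last available follow-up
stands in for it (the "last visit" convention for subjects who left
early).

**Quartiles.** Subjects are ranked ascending by fold-change and cut into
contiguous blocks whose sizes differ by at most one; remainder subjects
go to the *lowest* groups first (481 → 121/120/120/120). Ties break by
stable subject order — a convention of this package, since real tie
handling in the source tables is unknowable.

**Missingness** is handled complete-case per analysis stage; every stage
logs its exclusions. Unparseable numeric cells become missing at load
time and are reported in a load log, never silently zeroed.

## 2. Consensus learner selection

The feature roster for one visit pair is: per-protein baseline NPX and
NPX fold-change (deliberately distinct, separately selectable features),
baseline outcome, static clinical baselines (age, sex, smoker, diabetes,
coronary disease, QRS) and baseline + fold-change of the longitudinal
clinical variables (BMI, SBP, DBP, sodium, potassium, eGFR,
breathlessness score). Min–max scaling to [0, 1] is fitted on the
training partition only and applied unclipped elsewhere; fitting it on
all rows would leak test-set information into the tuning metrics.

The 80/20 split is stratified jointly by arm and outcome fold-change
quartile (the balancing variables were an open choice; arm × quartile
makes both partitions comparable on the two quantities the analysis
conditions on). Four learner families are tuned by mean 3-fold CV RMSE
over a grid; non-convergent grid points score +∞ rather than aborting.
The "conditional random forest" slot is a standard permutation-importance
random forest and the network is a small feed-forward regressor
(scikit-learn), since the pipeline's contract is *four diverse learners +
permutation importance*, not a particular tree or network variant; all
grids are config-exposed because no authoritative grid exists.

Permutation importance of feature *f* is the mean increase in RMSE over
`n_perm` independent shuffles of that column (negative values allowed).
It is computed by a batched implementation (stacked permuted copies
predicted in chunks) because per-call prediction is infeasible at 1000
permutations × ~550 features; the batched estimator is cross-checked
against scikit-learn's reference implementation in the test suite. By
default importance is evaluated on the training partition; a flag
switches to the held-out partition, which is cheaper and unbiased for
features the model ignores.

Consensus: the top `⌈0.10·p⌉` features per learner (ties by importance
then name), kept when supported by ≥ 2 of 4 learners, then intersected
across the two follow-up visits. Venn logic is per-visit consensus first,
cross-visit intersection second.

## 3. Mediation

All candidate fold-changes enter one OLS "signature score"; exact
collinearity drops the offending column with a log entry, and p ≥ n is
refused (the design targets p ≪ n). The estimator is the closed-form
product-of-coefficients for the linear no-interaction system:

    S ~ T + Z        → α₁ (treatment → score)
    Y ~ T + S + Z    → β₁ (direct), β₂ (score → outcome)
    ACME = α₁β₂, ADE = β₁, TE = ACME + ADE, proportion = ACME/TE

with subject-level nonparametric bootstrap percentile CIs. A
quasi-Bayesian simulation estimator would coincide with this for linear
models, and percentile bootstrap is what the downstream conventions
report, so the closed form is used and is verified in tests against an
explicit counterfactual-prediction computation of
`E[Y(1, M(1))] − E[Y(1, M(0))]` (equal to machine precision).

Pretreatment covariates default to the baseline outcome plus baseline
values of all candidate mediators; the eGFR fold-change can be added (it
appears in the screening models). Candidate screening uses (i) the
treatment effect on each protein's log2 change, adjusted for its baseline
and the eGFR fold-change, fitted with subject random intercepts across
the two follow-ups, and (ii) the treatment × protein-fold-change
interaction on the outcome fold-change.

**Leave-one-out proportion loss.** For mediator *j*, the score is refit
without *j*, the mediation rerun, and the reduced proportion subtracted
from the full one. Within each bootstrap replicate the same subject
resample feeds the full and every reduced model, making each loss a
paired difference (variance reduction; matches the "rerun" semantics).
Known behavior: two duplicated mediators each get loss ≈ 0 because
removal of one is compensated by its twin — the loss measures *unique*
contribution.

**Scales.** The outcome fold-change is analyzed raw by default; a log
option exists, and on the log scale (with mediators as log2 NPX changes)
the generator's structural model is exact, which the recovery tests
exploit. When |TE| falls below 1e-8 or ACME and TE disagree in sign the
proportion is reported as-is with an `unstable` flag.

## 4. Trajectories

Each biomarker is fitted separately with `value ~ time` REML mixed
models, correlated random intercept and slope per subject; the
subject-specific slope is the fixed slope plus the BLUP deviation.
Singular random-effect covariances fall back to independent random
effects, then to a documented two-stage fallback (per-subject OLS slopes
with empirical-Bayes shrinkage `λ_i = τ²/(τ² + v_i)`). Time is coded in
months, so slopes are per month.

Slope-on-slope regressions adjust for age, sex, arm and baseline eGFR,
report a joint F-test for the two protein-slope coefficients, emit
model-adequacy diagnostics (residual SD, residual-vs-fitted correlation,
Jarque–Bera statistic, max Cook's distance), and *always* compute a
robust Huber M-estimation refit with a divergence flag (coefficient moved
by > 1 OLS SE) — "refit when necessary" is subjective, so the package
computes it unconditionally and flags divergence. Prediction surfaces
hold covariates at their sample means.

## 5. Trend, interaction and enrichment statistics

Cochran–Armitage uses equally spaced scores 1..k by default
(configurable) and the two-sided asymptotic normal reference; note that
an exact conditional-permutation p is a *different* reference
distribution and does not coincide with the asymptotic one even on
moderate tables, so the test suite validates against a brute-force score
test (numeric differentiation of the binomial likelihood), which targets
the same reference. Trend p-values in summary tables are reported
unadjusted (matching the reporting convention of such tables) with a BH
column alongside.

Enrichment is upper-tail hypergeometric (`P(X ≥ k)` for k query hits, K
term members, n query and N universe genes) with BH adjustment across
tested terms — verified equivalent to one-sided Fisher exact tests.
Annotations come from GMT files only; term membership depends on
database release, so enrichment outputs are structural, never
value-anchored. Symbol matching is exact after case-folding; unmatched
symbols are warned about, never silently dropped.

## 6. The synthetic generator's stated world

Defaults mirror the motivating trial design: 488 subjects, 1:1
randomization, 276 NPX proteins, visits at 0/1/9 months. Baseline
clinical distributions are typical of an elderly at-risk-of-heart-failure
population (age ≈ 73 ± 6.5, 74% male, eGFR ≈ 74 ± 16, baseline outcome
median ≈ 80 µg/L log-normal). The structural model:

* mediator *j*'s log2 change at a follow-up = `a_j·T` (persistent by
  default; configurable decay at visit 2) + covariate terms + subject
  random slope × time + noise (SD 0.25);
* non-mediator protein changes are noise around subject random slopes;
* log outcome fold-change = `c·T + Σ_j b_j·Δ_j` + covariate terms +
  noise (SD 0.10), exponentiated for storage so fold-changes stay
  positive and the linear system is exact on the log scale;
* echocardiographic slopes = κ·(designated protein random slopes) +
  noise, giving genuine slope–slope coupling for the trajectory stage;
* eGFR fold-change carries a small treatment effect (−0.02 log units) so
  that eGFR adjustment is non-trivial.

Default mediation coefficients give ACME −0.078, ADE −0.052, TE −0.13,
proportion 0.6 — a treatment that lowers the outcome ~12% with most of
the effect routed through the panel, in the qualitative range of the
motivating analyses. Age, sex and eGFR enter both mediator and outcome
equations so covariate adjustment matters. The breathlessness score is
clipped to [1, 10] so its ratio fold-change is always defined.

What the generator does **not** emulate: empirical protein–protein
correlation structure (independent baselines; block correlation would be
a config extension), panel composition, assay floor effects (no LOD
imputation), informative dropout. A green recovery test therefore
establishes estimator correctness under the stated linear world, not
robustness to those real-data features.

## 7. Numerical choices and limitations

* `ACME + ADE = TE` is asserted to 1e-10 on every fit; TE equals the
  covariate-adjusted total-effect regression coefficient exactly
  (algebraic identity for nested OLS).
* Bootstrap replicates with undefined proportion (|TE| ≤ 1e-8) are
  excluded from the proportion CI only.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); fixed seeds give byte-identical exports.
* Proportions outside [0, 1] (opposite-sign ACME/TE) are reported as-is
  with a stability flag rather than truncated.
* The mediated proportions of the motivating analyses (0.70 / 0.58 /
  ~12%) are properties of unavailable individual-level data; they anchor
  qualitative behavior only and are not test targets.
* The pipeline is plain sequential execution with checksum checkpoints;
  no workflow-engine integration, no survival/prognostic modelling, no
  SHAP/partial-dependence explanations.
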