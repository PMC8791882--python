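# Methods

`periotree` implements a prognostic pipeline for 10-year tooth loss in
periodontitis patients after active periodontal therapy (APT), observed
through the supportive-therapy (SPT) maintenance phase.  The modelling unit
is the tooth; teeth are clustered within patients, and every stage of the
pipeline respects that nesting.

## The model: a logistic model-tree with a patient random intercept

For tooth *j* of patient *i*, the 10-year loss indicator is modelled as

    y_ij | b_i ~ Bernoulli( invlogit( beta_{leaf(ij)} + b_i ) ),
    b_i ~ N(0, sigma_b^2),

where `leaf(ij)` is the terminal node of a binary tree over the tooth- and
patient-level covariates, each leaf carrying a single intercept (terminal
groups are risk strata, not regressions), and `b_i` is a shared patient
random intercept.  Fitting alternates:

1. **Tree growth** with the current predicted patient effects held fixed as
   offsets.  At each node a score-type *instability test* probes the
   association between the working residuals `y - p_hat` and each candidate
   covariate.  Because leaves carry intercept-only models, the model score
   reduces to the working residuals, so the full M-fluctuation machinery of
   model-based recursive partitioning collapses to residual-association
   tests, which are exactly specifiable and testable:
   - *nominal* covariates: chi-squared statistic on per-level residual sums
     with the efficient-score covariance `diag(W_l) - w w'/W` (the node
     intercept profiled out), df = levels − 1;
   - *ordinal and numeric* covariates: maximum standardised cumulative
     residual sum over order-respecting cutpoints, Bonferroni-corrected
     over the number of cutpoints.

   P-values are Bonferroni-adjusted across the candidate variables with at
   least two observed levels in the node; the node splits on the smallest
   adjusted p-value below `alpha`.  The cutpoint itself is chosen by
   exhaustive binomial-deviance search (for nominal covariates the levels
   are first ordered by observed event rate — for a Bernoulli outcome this
   ordered scan attains the exhaustive-subset optimum).  Ties in deviance
   are broken toward the more balanced split, then lexicographically.
2. **Mixed-model estimation** with the tree fixed: the marginal likelihood
   of the random-intercept logistic model (one intercept per leaf) is
   maximised by adaptive Gauss–Hermite quadrature.  Adaptive (mode-centred,
   curvature-scaled) quadrature was chosen over penalised quasi-likelihood
   because it is accurate for binary outcomes at the cluster sizes seen
   here (10–28 teeth per patient) and admits a direct refinement self-check
   (15- vs 31-node log-likelihoods agree to <1e-3 on the recovery fixture).
   Patient effects are posterior modes ("BLUPs"), which become the offsets
   of the next growth pass.

The outer loop stops when the leaf assignment of all teeth is unchanged, or
the marginal log-likelihood improves by less than `ll_tol`, whichever comes
first; assignment stability is the tree-specific fixed point.

Ordinal covariates (bone loss, infrabony depth) are split as ordered by
default, because the published tree's splits are order-consistent; an
`ordinal_as_nominal` flag removes the restriction.  Age enters as a numeric
partitioning variable — the 61-year dichotomy of the published tree must be
*discovered* from data, never hard-coded into the learner.

### Tuning parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.05 | node split significance level |
| `bonferroni` | on | adjust across candidate variables per node |
| `min_node_size` | 50 teeth | smallest admissible child; makes ~8 leaves attainable on ~2500 teeth |
| `max_depth` | 5 | the published tree needs depth 4 |
| `quadrature_points` | 15 | adaptive GH nodes; refinement-stable |
| `ll_tol` | 1e-4 | outer-loop likelihood tolerance |
| `max_numeric_splits` | 64 | rank-space candidate grid for high-cardinality numeric variables, plus the widest-gap midpoints; exhaustive below that |

No tuning values are published for the original analysis; these defaults
are this package's own choices, all config-exposed.

### Numerical choices and degenerate inputs

- Leaf log-odds are bounded to |beta| ≤ 12 (p within ~6e-6 of the
  boundary), which keeps pure leaves finite and the likelihood well
  defined.
- `sigma_b` is estimated on [0, 8] with the boundary allowed; below 1e-8
  the model collapses to independent binomials, whose per-leaf MLE is the
  closed-form `logit(rate)` (used as an exactness oracle in tests).
- A cohort with all outcomes identical yields a root-only model with a
  warning, not a crash.
- Marginal (new-patient) predictions integrate `invlogit(beta + b)` over
  `N(0, sigma_b_hat^2)` with 41-node Gauss–Hermite quadrature; conditional
  predictions plug in the patient's posterior mode and fall back to the
  marginal for unseen patients.

## Bootstrap variable selection

200 patient-level bootstrap replicates (same number of patients, drawn with
replacement; each drawn copy a fresh independent cluster carrying all the
patient's teeth).  A variable occurs in a replicate if it appears in any
split of that replicate's tree (per-model counting, not per-split).
Inclusion is strict and asymmetric: tooth-level variables at frequency
> 0.5, patient-level at > 0.25 — looser for patient covariates because
patient-level resampling limits their variability.  Replicates whose mixed
fit fails are excluded from the denominator with a warning (counting them
as non-occurrence would bias frequencies down for reasons unrelated to
signal); more than 10% failures is a hard error.  The final model refits on
the full data restricted to the selected variables.

## Cross-validation and intervals

Ten folds split *by patient* (equal patient counts within one; tooth counts
differ), so no patient's teeth appear on both sides of any fold.  Test-fold
teeth belong to unseen patients and therefore get marginal predictions.
AUC is the rank-based Mann–Whitney statistic with average ranks for ties.
The sensitivity/specificity threshold is not published; the default policy
maximises Youden's J on the *training* fold and applies that threshold to
the test fold (the least arbitrary self-contained choice; a fixed threshold
is available).  Ties in J resolve toward the larger threshold, favouring
specificity — the clinically preferred error here.  With all scores equal
the policy classifies everything positive, giving (sensitivity,
specificity) = (1, 0).

Fold means are unweighted.  95% confidence intervals are Wilson score
intervals computed with n = the number of independent patients.  Applying a
binomial interval to a cross-validated mean is unorthodox and conservative;
it is reproduced deliberately because it is how the published metrics are
reported, and it reproduces all three printed intervals exactly from the
printed means (0.77 → [0.68; 0.84], 0.73 → [0.64; 0.80], 0.79 →
[0.70; 0.86] at n = 110).  The CV validates the *fixed* selected variable
set (whether the original analysis re-ran selection inside each fold is not
stated; re-selection per fold can be composed manually from the API).

## The published risk calculator

The final published tree is encoded verbatim as a fixed classifier: five
covariates (merged bone-loss category, furcation class, abutment status,
age, diabetes) route a tooth to one of eight groups with the printed
empirical rates.  Age exactly 61 follows the low-risk branch ("≤ 61").
The printed group totals sum to 2529 teeth / 161 lost while the
accompanying text reports 2528 / 166; the calculator reproduces the printed
rows and surfaces, rather than resolves, this discrepancy.  Totality and
uniqueness of the routing are proven by exhaustive grid enumeration, and a
serialized tree encoding the same splits routes identically (cross-module
equivalence test).

## The synthetic-cohort generator

The study's raw data are not deposited, so the generator produces cohorts
with the statistical structure the analysis assumes, calibrated to the
published descriptive tables:

- **Patient level:** 110 patients by default; 61.8% female; 8.2% diabetic;
  smoking never/former/active = 45.5/24.5/30.0%; age ~ N(46.7, 10.26²)
  truncated to [18, 90]; PCR ~ N(31.3, 17.39²) clipped to [0, 100] and
  missing with probability 7/110.
- **Dentition:** each of the 28 FDI positions (third molars excluded) is
  present independently with a type- and jaw-specific probability
  `q(type, jaw) = p_type · mean_teeth · 2 p_jaw / slots_type`, so the
  expected tooth-type and jaw shares equal the configured marginals exactly
  and the expected dentition size is `mean_teeth` = 23.2.  Counts
  concentrate in roughly 17–28 teeth.  This presence model was preferred
  over drawing a tooth count first because capped-multinomial schemes
  distort the type marginals the tests must recover.
- **Tooth level:** furcation is sampled conditionally on tooth type
  (anterior teeth always single-rooted; molars always multi-rooted;
  premolar/molar FI shares derived from the published furcation totals);
  raw bone loss, infrabony depth and abutment status are sampled
  independently of type from the published totals.  The joint distribution
  of tooth covariates is not published; the hierarchical-then-independent
  scheme is this package's choice, and conditional tables can be injected
  through the config.
- **Missingness** mirrors the published complete-case accounting
  (2528 of 2556 teeth): bone loss missing at 28/2556, furcation and
  abutment missingness nested inside the bone-loss-missing set.
- **Outcome:** the tooth's published group is computed by the risk
  calculator; group offsets eta_g are calibrated by quadrature + root
  finding so the *marginal* loss probability equals the published group
  rate (exact lost/total fractions) for the configured `sigma_b`; the
  outcome is Bernoulli at `invlogit(eta_g + b_i)`.
- `sigma_b` defaults to 0.5 — visible but moderate clustering.  The
  original analysis reports no random-effect variance, so this is a free
  simulation parameter, not a reproduced quantity.
- Gender, smoking, PCR, jaw, tooth type and infrabony depth carry **no
  effect** by default (they are not in the published tree); `extra_effects`
  injects logit-scale effects for selection-power experiments, and
  `null_rate` produces an effect-free cohort.

What passing tests on these cohorts do and do not show: they demonstrate
that the pipeline recovers a known mechanism of exactly this shape —
published-group risk structure, logistic-normal clustering, independent
covariates.  Real cohorts have correlated tooth covariates (e.g. bone loss
with furcation involvement), informative missingness, and patient effects
that need not be Gaussian; performance numbers on synthetic cohorts
(CV AUC ≈ 0.65–0.75 at n = 110) characterise the pipeline, not the
published cohort, and the published naive-vs-CV contrast is checked only as
a qualitative majority property over seeds.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen for tight Monte-Carlo error at
interactive runtimes: marginal recovery at 2000 patients; group-rate and
tree-structure recovery at 5000 patients; random-intercept recovery at
1000 patients × 20 teeth; bootstrap-selection power at 50 patients × 200
replicates; split-level type-I control at 150 patients × 60–100 effect-free
replicates; the naive-vs-CV contrast over 20 seeds at the study size
(110 patients, 10 folds).

## Known limitations

- Intercept-only leaves: no random slopes, no continuous leaf models, no
  time-to-event structure (the outcome is the single 10-year binary).
- The instability test conditions on the current patient-effect offsets
  rather than refitting the mixed model under each candidate split;
  this is the standard alternation and is what makes split-level type-I
  control testable, but it is approximate when clustering is strong.
- Wilson intervals around CV means inherit the published (conservative,
  non-standard) interpretation; they are not bootstrap intervals.
- The generator's independence assumptions above.
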