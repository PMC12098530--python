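# Methods

## Problem setting

Binary low-prevalence predictors (LPPs) — screening criteria, risk factors
or clinical signs present in fewer than 10% of subjects — are ubiquitous in
clinical cohorts, and they destabilise classical variable selection:
maximum-likelihood logistic coefficients for rare indicators have inflated
standard errors and are prone to quasi-complete separation, while
tree-ensemble importance measures depend on how often a rare predictor is
even offered to a split. `lpp_select` implements and compares two selection
procedures on binary cohorts of this kind, together with a simulation
harness that varies the marginal prevalence of the predictors while holding
their effects fixed.

## Generating model (`synthetic_data`)

Cohorts are drawn from a logistic model over `p = 32` independent Bernoulli
predictors,

    x_ij ~ Bernoulli(pi_j),
    y_i | x_i ~ Bernoulli( expit( b0 + sum_j beta_j x_ij ) ).

Defaults emulate a paediatric sepsis screening cohort: `n = 3473` subjects,
target outcome prevalence 15.1%, and 32 criteria in four categories (9
sepsis indicators, 6 risk factors, 8 severe and 9 moderate illness
features), of which 18 have prevalence < 10% and 12 have prevalence <= 5%.
The default `beta_j` are the logs of the full-model odds ratios estimated
on that cohort (e.g. lactate >= 2 mmol/L: OR 6.30; age < 3 months: 4.60;
hypothermia: 6.89). The cohort's per-predictor prevalences are not public,
so the shipped prevalence table is a declared surrogate satisfying the
category and LPP counts; the handful of published values (hypotension 1%,
capillary refill 4%, recent trauma and low glucose <= 4%) are used
directly, hypothermia is set to 1% consistent with its very wide published
confidence interval, and everything is overridable via YAML predictor
specs (odds ratios accepted on the natural scale).

**Intercept calibration.** `b0` is solved from
`E[expit(b0 + sum beta_j x_j)] = target` by Brent root search over one fixed
Monte-Carlo draw of 200,000 predictor vectors (deterministic given its
seed; tolerance 1e-10 on the log-odds scale, which maps to far below the
±0.005 prevalence tolerance the generator promises). With all-null betas
the closed form `logit(target)` is returned.

**Correlation.** Predictors are independent by default — the real cohort's
joint distribution is unknown and inventing one would be worse than
declaring independence. A latent-Gaussian (thresholded copula) correlation
matrix can be supplied for sensitivity analyses; it preserves each
marginal prevalence exactly.

**What the generator does not emulate:** missingness, continuous
predictors, category-structured correlation (e.g. the overlap between
"parental concern" and the combined "parental/healthcare-worker concern"
criterion), or any real-data drift between sites or seasons. Passing tests
therefore show that each procedure behaves as designed under the declared
generating model, not that it would select the same variables on the real
cohort.

## ROC statistics (`roc_stats`)

The AUC is the Mann-Whitney statistic (ties half-credited), computed by
midranks in O(n log n); it equals the trapezoidal area under the empirical
ROC curve (checked against an independent trapezoid implementation to
1e-12). DeLong's test for two correlated ROC curves operates on placement
values: for positive i, `V10_i` is the fraction of negatives it outscores.
Variances and the covariance of the two AUC estimators are sample
(co)variances of the placement vectors scaled by the class counts, and

    z = (AUC1 - AUC2) / sqrt(var1 + var2 - 2 cov12)

is referred to the standard normal, two-sided. A zero-variance difference
(self-comparison) returns z = 0, p = 1 rather than NaN. Confidence
intervals for a single AUC use the stratified bootstrap: positives and
negatives resampled separately with replacement (class counts preserved,
so no replicate loses a class), percentile interval, default 2000
replicates at alpha = 0.05. The percentile flavour was chosen as the
simplest scheme consistent with stratified resampling; the method is
recorded on every `AucEstimate`.

## Random-forest selection (`rf_selection`)

Importance is the **unscaled** permutation importance: for each tree, the
drop in accuracy on that tree's out-of-bag subjects when one predictor's
values are permuted among them, averaged over trees. The scaled variant
(divided by its standard error) is deliberately avoided — its
normalisation distorts comparisons between predictors of different
prevalence. scikit-learn does not expose per-tree out-of-bag permutation
importance, so it is computed here directly: each tree's bootstrap draw is
reconstructed from its recorded random state (verified in tests against
the library's own out-of-bag bookkeeping), and permutations are applied
per tree per predictor.

The selection procedure averages importances over 25 independent forests
of 10,000 trees (full-scale defaults; tests use smaller forests),
ranks predictors by the averaged importance (ties broken lexicographically
by name so reruns are identical), removes predictors with non-positive
importance, then builds nested models on the top-k ranked predictors for
k = 3 upward. Each nested model is scored by pooled out-of-fold
predictions from stratified 10-fold cross-validation — a subject's score
is the fraction of trees voting class 1 in the forest trained without its
fold, uncalibrated — and compared to the full reference model (ALL
candidate predictors, not merely the positive-importance ones) with the
paired DeLong test. **One fold assignment is shared by every nested model
and the full model within a run**; without that the DeLong pairing would
be invalid. The parsimonious model is the smallest k whose p-value is at
least alpha = 0.05; when no sub-model qualifies the result records
`chosen_k = None` (the large-mtry outcome, where sub-models underperform
the full model). An `mtry` sweep over {3, 6, 16} (small, sqrt(p), large)
runs the whole procedure per value with independent derived seeds.

Pooling out-of-fold scores (rather than averaging per-fold AUCs) is a
design choice: pooling yields one score per subject, which the paired
DeLong test requires. The full reference model is re-trained per fold
under the same folds.

## Stepwise regression (`stepwise`)

Forward and backward greedy selection on AIC
(`AIC = 2 k - 2 log L`, intercept included in k). Backward starts from the
full model and removes the predictor whose removal lowers AIC most;
forward starts from the intercept and adds the predictor that lowers AIC
most; both stop when no move lowers AIC. Ties within 1e-8 prefer the
smaller model; ties between candidates break lexicographically. No
p-value stopping rule is used anywhere. Effects are reported as Wald odds
ratios with `exp(coef ± z SE)` intervals.

Fits use Newton/IRLS maximum likelihood (statsmodels). Separation — any
|coefficient| above 15 on the log-odds scale, or non-convergence — is
flagged, and flagged intervals are marked unreliable but still reported;
no penalised (Firth-type) fallback is applied, so unstable rare-predictor
estimates remain visible rather than silently shrunk. When the Newton
Hessian is exactly singular (a constant column or complete separation in
a small stratum) a pseudoinverse IRLS fallback supplies a finite, flagged
fit so greedy search can continue; such models carry an AIC penalty for
the useless parameter and are eliminated naturally.

Selection runs once on the full data; the retained set is then
cross-validated as a fixed set (coefficients refit per training fold,
pooled out-of-fold probabilities). The optimism this induces — the folds
never re-run the selection — is the standard caveat of reporting a
selected model's CV AUC and is deliberate, mirroring common practice.

## Simulation harness (`simulation_harness`)

Four arms: the original prevalences and floors of 10%, 20%, 30%
(`pi_j <- max(pi_j, floor)`; betas unchanged). Per arm, `n_datasets`
cohorts are generated; each cohort is analysed by (a) ONE forest (not the
25-repeat average) whose permutation-importance ranks 1..32 are recorded,
plus a pooled out-of-fold CV AUC, and (b) one stepwise run (backward by
default) whose retained set and retained-model CV AUC are recorded.
Aggregates are the per-predictor rank distributions, retention counts,
and per-arm AUC mean/SD.

The intercept is **recalibrated per arm** so the outcome prevalence stays
at its target; otherwise raising the prevalence of positive-effect
predictors would inflate the outcome rate and confound the AUC trend with
a case-mix shift. A fixed-intercept mode is available by flag. Both arms
consume identical cohorts (identical derived seeds), so arm differences
are method differences. Per-dataset JSON checkpoints make long runs
resumable, and aggregation is order-independent.

**Problem sizes.** Full scale reproduces the 4 x 1000 design at n = 3473
with 10-fold CV and 500-tree forests (the forest library's default size;
the 10,000-tree setting belongs to the importance-averaging stage, not the
per-dataset simulation fits). The workstation ("desk") scale used by the
test suite runs 20 datasets per arm at n = 1200 with 5-fold CV and
300-tree forests — chosen as the smallest design in which the
prevalence-AUC trend is resolved well beyond its Monte-Carlo error on a
single CPU in minutes. Both scales are presets of the same code path.

## Numerical choices and edge cases

- All randomness derives from one master seed via `SeedSequence`-based
  counter hashing; any single cohort/forest/bootstrap is reproducible in
  isolation. Seeds handed to libraries stay below 2^31.
- Degenerate outcomes (all 0/1) are warned about by the generator and
  redrawn (up to 20 attempts, logged) inside the harness.
- A forest sub-model with fewer predictors than `mtry` caps the per-split
  candidate count at the subset size.
- Rank ties, AIC ties and importance ties all have declared deterministic
  tie-breaks (documented above) so reruns are byte-identical.
- Bootstrap percentile endpoints are clamped to contain the point AUC
  (relevant only for tiny degenerate samples).

## Known limitations

- Independence of predictors is an assumption, not an estimate; the
  copula option exists but no default correlation is claimed.
- No class-imbalance resampling and no hyperparameter search beyond the
  three a-priori mtry values — both are out of scope by design.
- The stepwise CV AUC is optimistic (selection outside the folds), and
  the forest vote-fraction scores are uncalibrated probabilities; both are
  adequate for AUC-based comparison but not for risk prediction.
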