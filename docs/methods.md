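# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `flowcpm`, and what the synthetic-data studies
do and do not establish.

## Behavioral scoring

**Forward flow.** Semantic distance is 1 − cosine similarity between
word-embedding vectors; the forward-flow score of a stream is the mean,
over positions 2…n, of the average distance from each thought to all
preceding thoughts. The distance functional is the standard choice of
the forward-flow literature; vectors are normalized implicitly by the
cosine, so embedding scale is irrelevant (a tested invariant). Words are
case-folded before lookup. Out-of-vocabulary responses are dropped with
a logged warning and n adjusted (configurable to raise instead), because
real transcripts contain typos and the statistic only needs resolvable
thoughts. The cue word is not counted as a thought; only responses
enter the stream.

**Associative ability.** Forward flow is z-scored across the cohort
within each task item, then averaged over items per participant.
Standardization uses the sample (n−1) SD throughout the package, with
`ddof` configurable; the two-participant worked example {1.0, 3.0} →
{−0.707, +0.707} follows that convention.

**AUT aggregation.** Ratings are averaged over responses within
(participant, item, rater), then over raters, then z-scored across the
cohort per item, then averaged over items. Averaging responses before
raters is one of two algebraically different orders for ragged response
counts; this order follows the task's scoring narrative and is fixed
here. Participants missing an item are excluded with a log entry.

**Stop-signal.** SSRT uses the integration method per SSD: the
p(respond|signal)-quantile of the go-RT distribution minus the SSD,
averaged over SSDs. The quantile is nearest-rank on the sorted go-RT
list — exactly reproducible by a brute-force oracle, which the tests
exploit. SSDs with zero respond-probability are skipped with a warning;
staircase extension SSDs beyond the four ladder values (140/180/220/260
ms ± 60 ms steps) are kept in their own per-SSD pools.

**Switching.** Switch cost = mean RT (switch) − mean RT (repeat),
correct responded trials only by default (`correct_only=False` uses all
responded trials); accuracy is the unweighted mean of the two per-type
correct fractions with no-response counted as incorrect.

**Composites and exclusion.** The three task RT scores are each
z-scored across the cohort and averaged (lower = better executive
function); likewise the three accuracies. Participants with any
standardized score beyond |z| = 3 are excluded, with an exclusion log.
Missing task scores propagate to listwise exclusion before modeling.

**Dissociation GLMs.** OLS on standardized variables. Model "1":
outcome ~ associative ability + EF-RT composite + EF-ACC composite (the
accuracy composite controls the speed–accuracy trade-off). Model "1x"
adds the association × EF-RT interaction; model "2" adds gender, age,
handedness. Bonferroni correction defaults to the number of focal
predictor tests per model (2 for models 1/2, 3 for 1x), configurable via
`family_size`. Rank-deficient designs raise a collinearity error naming
removable columns.

## Connectomes

Functional connectivity is the Fisher z (arctanh) of the Pearson
correlation between node time series; |r| is clipped at 1 − 1e-7 before
the transform so duplicated signals stay finite. Matrices are
symmetrized and the diagonal zeroed; all analyses operate on the
canonical row-major upper-triangle edge ordering (N(N−1)/2 edges, 44850
at N = 300). Node indices are 0-based in code and 1-based in files.
Masks refuse to apply against data with a different edge count. Block
task connectivity averages per-trial FC matrices element-wise within a
block. Time series are consumed pre-cleaned; no denoising is done here.

## Relevance vector regression

The learner is a sparse Bayesian regression over a linear kernel on
training samples plus a bias: y = Φw + ε, Gaussian noise precision β,
per-basis Gaussian prior precisions αₘ estimated by type-II maximum
likelihood. Fitting uses the sequential (fast marginal likelihood)
algorithm: single-basis add / re-estimate / delete actions, each chosen
as the largest analytic gain of the log evidence, with αₘ = sₘ²/(qₘ²−sₘ)
at the optimum. The sequential scheme was chosen over full-design
simultaneous updates because the linear kernel built from a handful of
selected edges is heavily rank-deficient, and simultaneous α updates on
near-duplicate bases can enter limit cycles instead of converging.

Numerical choices:

- sparsity/quality factors S, Q are computed as β times a Schur-
  complement form (the textbook β² Woodbury expression cancels
  catastrophically once β grows large), with the analytically
  non-negative S bracket floored at zero;
- a basis is never added while its absolute cosine with an active basis
  exceeds 1 − 1e-3 (alignment guard against a singular active Gram);
- the noise precision is re-estimated every 5 actions and again at
  structural convergence; the fit is accepted only once the noise
  estimate itself is stable (|Δ log β| < 1e-3);
- defaults: 500 actions maximum, re-estimation tolerance 1e-6 on log α,
  pruning ceiling α > 1e9 — all configurable.

With `update_hyperparams=False` the model skips evidence maximization
and solves the full design at fixed (α, β); the posterior mean then
equals the penalized-least-squares (kernel ridge) closed form with
penalty α/β, which the test suite uses as an independent oracle.

## CPM

Per cross-validation fold, every edge is correlated with the score in
the training participants only (Pearson, or partial Pearson controlling
mean framewise displacement / age / gender / handedness); edges with
two-tailed p below the threshold (default 0.01; 0.05 and 0.005 as
robustness variants) are split by sign and concatenated as the joint RVR
feature set (sign-separated models are available via the mask object).
Edge features enter on their Fisher-z scale without per-fold rescaling,
matching common CPM practice. A fold with empty selection predicts its
training mean, logged. Predictions are averaged over repetitions of the
fold loop (150 in the full design; scaled down in the studies below),
and the prediction r is the Pearson correlation of mean predictions with
observed scores.

The permutation null shuffles the participant↔connectome assignment and
reruns the entire pipeline; permutation reruns default to fewer
repetitions (10) than the observed analysis for tractability, which
leaves the null exchangeable because every permutation is treated
identically. p_pt uses the add-one convention (1+k)/(1+N), so beating
all 1000 nulls reports p_pt < 0.001.

Consensus masks retain edges selected (per sign) in strictly more than
80% of all folds pooled across repetitions; "more than" is read as a
strict inequality, so an edge at exactly 80% is dropped.

External validation fits one model on the full training cohort —
re-running selection at the configured threshold by default (fitting on
a supplied consensus mask is the alternative) — then reports the partial
Pearson correlation of predicted vs. observed scores in the new cohort
given its covariates, one-tailed for a positive association. Task
validation predicts per block, computes each participant's Spearman ρ
against observed block scores, builds a within-participant null by
shuffling the block assignment, and compares ρ against the null means
with a one-tailed Wilcoxon signed-rank test.

Specificity profiles correlate model predictions with an outcome
battery under pairwise deletion, rank outcomes by |r| and report η² as
the squared correlation — the proportion-of-variance effect size, which
is unaffected by per-outcome sample size.

## Mediation

Three OLS fits (M~X; Y~X+M; Y~X) on z-normalized variables (an
unstandardized mode exists); indirect = a·b; case-resampling bootstrap
(participants, with replacement, default 1000 draws) with percentile
intervals at 95% and 90% coverage — the 90% interval is reported because
one pathway of interest is marginal at 95%. The identity c = c′ + a·b
holds to 1e-10 by construction of OLS on a common sample and is
regression-tested. Covariates do not enter the mediation models by
default.

## Synthetic data: what it emulates, what it does not

The study's human data (behavioral tables, resting and task fMRI) are
not publicly deposited, so the generators produce every input with known
structure:

- **Embeddings** are uniform on the unit sphere — cosine geometry is
  well behaved but there is no semantic clustering, polysemy or
  frequency structure.
- **Thought streams** repeat the previous word with probability
  1 − flow_level and otherwise jump with probability tilted toward
  distant words (softmax with concentration 4); flow_level monotonically
  controls expected forward flow, and 0 forces repetition (flow exactly
  0). Real streams have topical coherence this ignores.
- **Behavioral cohorts** follow the linear-Gaussian model the GLMs
  assume, with default standardized effects 0.12 (association→novelty),
  −0.09 (EF-RT→appropriateness), −0.09 (association→appropriateness),
  unit residual SD, and no planted interaction (none was found
  significant). After marginal standardization the recoverable
  coefficients are attenuated by the outcome SD (≈0.7% here), which the
  recovery study accounts for analytically. Gender is Bernoulli(0.67
  female) and handedness Bernoulli(0.9), echoing the cohort composition;
  both are cosmetic.
- **Connectomes** inject the planted effect additively on the Fisher-z
  edge scale — the scale the pipeline analyzes — as
  effect_size·z(behavior) plus orthogonal noise, so the planted
  edge–behavior correlation equals ±effect_size in expectation.
  The default effect size (0.4) and per-edge noise SD (0.3) are chosen
  for test power at desk-scale cohorts, not for physiological realism;
  real edge–behavior couplings are far weaker and the paper-scale
  prediction r (~0.1 at n≈1500) is correspondingly far below what these
  planted cohorts produce.
- **Stop-signal trials** follow an independent race model with Gaussian
  go RTs (truncated at 50 ms), a constant stop latency, and the
  staircase SSD procedure. The integration-method estimate carries a
  small positive bias (~20 ms) at these trial counts, within the ±30 ms
  recovery band the studies check.
- **Task blocks** shift each block's Fisher-z pattern along the fitted
  model's prediction gradient by coupling·score and generate Gaussian
  trial windows with the implied correlation structure (eigenvalue-
  clipped to the positive-definite cone). There is no hemodynamic
  response, autocorrelation or spatial structure — by design, at most
  noise-plus-signal.

Passing tests therefore establish that the *pipeline* is correct and
calibrated — selection FPR matches its threshold, permutation p values
are uniform under the null, planted structure is recovered with the
stated power — not that real fMRI data would yield any particular
effect size.

## Study sizes

The simulation studies run at sizes chosen to keep the full suite
within a few minutes on one CPU while preserving the statistical content
of each check:

- permutation calibration: 50 replicates × (n = 100, 20 nodes, 5 folds,
  100 permutations), KS test against uniformity at α = 0.01;
- CPM recovery: 10 replicate seeds × (n = 200, 30 nodes, 20 planted
  edges at effect 0.4, 10 folds × 20 repetitions, 99 permutations);
- GLM recovery: 100 replicates at n = 2000, 95% CI coverage per planted
  path;
- mediation coverage: 200 replicates at n = 500 with 1000 bootstrap
  draws each;
- SSRT recovery: 50 seeds at the full trial count (192 go + 64 stop).

Every random draw descends from a single seed through spawned child
seeds, so all studies and the end-to-end pipeline are bit-reproducible.

## Known limitations

- The RVR implements regression only (no classification) and only the
  linear kernel, the customary choice for connectome prediction.
- Partial correlation p-values assume Gaussian residuals; no rank-based
  selection variant is provided.
- The mediation module handles a single mediator without covariates;
  moderated or multiple mediation is out of scope.
- The pipeline consumes cleaned node time series or FC matrices;
  acquisition, preprocessing and parcellation live upstream.
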