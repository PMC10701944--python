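# Methods

`attnrisk` implements a complete clinical-prediction workflow for
longitudinal coded health records: featurization of event streams anchored
at an index date, static baselines, two attention-based sequence models
(one recurrent, one transformer, the latter optionally pre-trained by
reverse distillation from the linear baseline), class-weighted training,
and an evaluation layer covering discrimination, calibration and clinical
utility.  This note records the modelling assumptions, the defaults and
why they were chosen, and the numerical decisions that were genuinely
open.

## Data model and featurization

An *observation* is a (person, index date) pair with a binary outcome
ascertained over a fixed time-at-risk after the index date, plus age and
sex.  Predictors are drawn from the 365 days up to and including the
index date.  Two views are built from the same events:

* **Static view.** For lookback windows of 365, 180 and 30 days, column
  (concept, window) is 1 iff the concept occurs in `[index - w, index]`.
  Windows are inclusive at both ends: "until the index date" is read as
  including it, and index-date events are kept by default (a
  `include_index_date` flag exists because index-date coding can leak
  label information in some extraction pipelines).  Scaled age and a sex
  indicator are appended.  Columns present in fewer than 0.1% of
  observations are dropped (strictly-less-than removal, so a feature at
  exactly 0.1% survives).  Age is max-abs scaled to [0, 1] with the
  divisor fit on *training* rows only and reused downstream; held-out
  values may therefore exceed 1 slightly.  This train-only fit is not
  strictly necessary for a max-abs divisor but removes any route for
  test-set information to enter preprocessing.
* **Temporal view.** One visit per calendar date per person (GP-record
  granularity; flat files carry no visit table), holding the deduplicated
  set of concepts coded that day and its day-offset before index.  Visits
  are ordered oldest-first.  Sequences are capped at 50 visits by default,
  truncating the *oldest* visits; batches are padded and masked.
  Observations with no qualifying events keep their static covariates via
  a learned null-visit token.

Splits randomize *persons*, never observations, 75/25
development/test and then 67/33 train/validation inside development, so
multi-visit patients cannot straddle folds.

## Models

**L1 logistic regression.**  The regularization strength is chosen by
3-fold stratified cross-validated log loss over a 20-point geometric path
(a simple, transparent stand-in for adaptive regularization-path search,
which is a black-box detail of the original tooling), then refit on all
development rows.  The unpenalized intercept is polished to its exact
profile MLE after the solver finishes, so mean fitted risk equals the
training event rate.  The fitted coefficients also drive feature
reduction: the top-k features by |coefficient| (ties to the lower column
index) define reduced feature sets.

**Gradient-boosted trees.**  XGBoost with exhaustive grid search over a
small grid, selected by the same 3-fold CV log loss.

**RETAIN-style recurrent attention.**  Concept embeddings are summed per
visit; age, sex and the visit time (days-before-index / 365 — the
original recipe concatenates "visit times" without fixing an encoding, so
the simplest bounded one is used) are concatenated.  Two bidirectional
LSTMs read the sequence: a scalar softmax attention over visits comes
from one, a per-coordinate tanh gate from the other, and the context
vector is the attention-weighted sum of gated visit embeddings, fed to a
logistic output layer.  The original unidirectional model processes time
in reverse; with bidirectional LSTMs (reported to help, and used here)
direction is moot.  Padded visits carry exactly zero attention weight.

**Transformer.**  Visit embeddings (with statics concatenated per visit,
matching the recurrent model's treatment, then projected to the model
width) receive a sinusoidal embedding of the day offset, pass through a
stack of *pre-norm* multi-head self-attention blocks (pre-norm chosen for
small-batch training stability), and a convolutional prediction head (two
kernel-3 1-D convolutions, masked max-pool over time, linear).  A
diagnostic mean-pool head is available; with it, permuting visits
together with their time offsets provably leaves the score unchanged,
which the tests exploit.

**Reverse distillation (SARD).**  The transformer is first trained to
match the linear baseline's logits on the training fold (mean squared
error on logits — the distillation loss form is not pinned down by the
original description; MSE on logits matches "predictions" exactly at
convergence and is scale-stable), then finetuned on the validation fold
with loss `alpha * MSE(student, teacher) + (1 - alpha) * weighted BCE`.
`alpha = 1` is pure distillation, `alpha = 0` pure label training; high
alpha constrains the student near the linear model.  Finetuning on the
validation fold follows the original recipe; that fold is later reused
for recalibration, a methodological caveat we keep because the protocol
specifies it.

These networks run on a small reverse-mode autodiff engine written on
numpy inside the package (`autodiff.py`, `nn.py`): a tape of vectorized
array operations with hand-written backward rules, verified against
finite differences in the test suite.  Model dimensions are deliberately
small (default embedding 16, one attention layer) — appropriate for the
synthetic cohort sizes used here; everything is configurable.

## Training

The objective is weighted binary cross-entropy with the positive-class
weight equal to the negative:positive ratio of the training fold.
Optimization is minibatch Adam (batch 512 by default; the benchmark
fixtures use 128, because at a few thousand training rows a 512-row batch
gives the optimizer only ~14 updates per epoch and the epoch-granular
stopping rules below then act on almost-untrained models).  Early
stopping has patience 3 on validation loss; the learning rate is divided
by 10 after one stagnant epoch (both counters reset on improvement; the
LR counter also resets after each cut).  Best-validation weights are
restored.  The final model is then *refit* on the full development fold
(train + validation), replaying the recorded LR schedule up to the best
epoch with no monitoring — this refit matters at desk scale, where the
extra 50% of training data is a material gain.  Distillation uses its own
step-decay LR schedule (start 1e-2, two cuts) rather than the
discriminative rate: the teacher-matching regression needs the higher
rate to reach high rank fidelity, and has no early-stopping interplay to
respect.  For the distilled model the refit re-runs the curriculum —
a shorter distillation then the alpha-blend finetune — on the
development fold.

Hyperparameter search is a lightweight tree-of-Parzen-estimators:
after a random startup phase, trials are split at the top-quartile of the
objective and candidates are sampled from a per-dimension Parzen density
over good trials, scored by the good/bad density ratio.  A pure
random-search backend is available.  The default desk-scale budget is 20
trials (the search-space definition and trial log match a 100-trial
protocol; budget is a flag).  Hyperparameter importance fits a random
forest mapping trial settings to validation AUC and attributes
predictions by *exact* interventional Shapley values (coalition
enumeration — feasible because there are few hyperparameters), so
additivity holds to float precision.

## Evaluation

* **AUC**: Mann-Whitney with ties at 1/2; CI from the DeLong variance via
  the fast midrank algorithm, normal interval clipped to [0, 1].
* **AUPRC**: average precision (step-wise; trapezoidal interpolation is
  biased for PR curves); CI on the logit scale with standard error
  `1/sqrt(n_pos * ap * (1 - ap))` (the interval family recommended for
  average precision; a bootstrap alternative sits behind a flag since the
  exact published variant is underdetermined).
* **Recalibration**: class-weighted training guarantees overestimated
  risk, so every model (baselines included, for fairness) gets Platt
  scaling — a slope and intercept on the logit scale fit by maximum
  likelihood on the validation fold.  On the fitting fold the logistic
  score equation forces mean recalibrated risk to equal the event rate.
  Constant scores leave the slope unidentifiable; an intercept-only fit
  is used with a warning.
* **Smooth calibration**: logistic regression of the outcome on a
  restricted cubic spline basis of logit(score), knots at Harrell's
  standard quantiles (5 knots at 0.05/0.275/0.5/0.725/0.95; the knot
  count drops automatically when there are few distinct scores), curve
  reported on the 1st-99th percentile score range with a density summary
  of where predictions live.
* **Decision curves**: net benefit `TP/N - FP/N * t/(1-t)` for "treat if
  score >= t", against treat-all and treat-none, on a default grid
  0.001-0.5 (step 0.001) — clinically useful thresholds for outcomes with
  1-10% prevalence sit well below 0.5.

## Synthetic cohorts

The generator emulates the regimes of the published cohort summaries
(outcome prevalence 1-10%, feature-matrix density ~1-2%): per person a
Poisson number of visits uniform over the prior year, a Poisson number of
concepts per visit from a long-tailed (shifted-Zipf) popularity
distribution, and a logistic outcome model with static concept effects, a
recency term (extra log-odds when a causal concept occurs within 30 days
of index) and an age effect.  The intercept is solved by bisection
(tolerance 1e-4) to hit the target prevalence; the realized per-person
risks are stored, so the oracle AUC — the discrimination ceiling — is
known for every fixture.  Defaults: 20,000 persons, 500 concepts, 8
visits/person, 3 concepts/visit, prevalence 0.05, five planted concept
effects with |log-odds| between 1 and 2 at moderately common popularity
ranks — chosen so that sign recovery by an L1 fit is statistically
comfortable at n = 20,000 but not trivial.

Because the recency term is carried by event *time*, the static view sees
an additive approximation of it through its window columns: static
baselines remain competitive by construction, mirroring practice.  With
the default 30-day recency horizon that approximation is in fact almost
exact — the horizon coincides with the 30-day feature window, so the only
structure a sequence model can add is the OR-over-concepts nonlinearity,
worth at most a point or two of AUC at these sizes.  The
temporal-advantage benchmark fixture therefore makes the recency term
dominant *and* temporally misaligned: boost 3.0 on the log-odds scale
over twelve common causal concepts, static effects at most ±0.3, and a
45-day horizon that falls between the 30- and 180-day feature windows.
The static model must then approximate a 45-day indicator with columns
that cut at 30 and 180 days, while the sequence models see exact day
offsets — the comparison measures temporal resolution, which is the
mechanism the fixture exists to probe, rather than optimizer noise.

What the generator does **not** emulate: medical ontologies and code
hierarchies, care pathways or visit-interval structure, informative
censoring, measurement features with missingness.  Passing tests
demonstrate that the machinery recovers known mechanisms at realistic
sparsity and imbalance — not that any architecture will rank the same way
on real records.

## Numerical details and edge cases

* Probabilities are clamped at 1e-7 before logs/logits throughout.
* Attention masking adds -1e9 to padded keys pre-softmax; in float64 the
  padded weights underflow to exactly 0, so normalization over real
  visits is exact rather than approximate.
* All-zero numeric columns are left unscaled with a warning; empty
  hyperparameter grids, single-class labels, negative windows and
  out-of-range fractions raise immediately.
* Degenerate calibration inputs (fewer distinct scores than knots,
  constant scores) degrade gracefully: knot reduction, then a flat curve
  at the event rate.
* The acceptance/benchmark scripts scale cohort sizes to desk scale
  (thousands to twenty thousand observations, small model dims); the
  problem sizes are stated next to each computed number.

## Known limitations

* The autodiff engine is CPU/float64 only; training cost grows linearly
  in sequence length and it is not intended for cohorts beyond ~10^5
  observations.
* The TPE implementation treats dimensions independently (no joint
  density), which is standard but can be inefficient for strongly
  interacting hyperparameters.
* Person-level splitting assumes person ids are consistent across the
  event and cohort tables; no record linkage is attempted.
* The graph-attention architecture family is out of scope, as is any
  database connectivity: inputs are flat delimited files.
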