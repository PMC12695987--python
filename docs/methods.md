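# Methods

## The certainty / action-threshold model

The core model (`vwmdyn.mom`) treats a memory trace as a scalar
*certainty* c ∈ [0, 1]:

* **Build-up.** c(v) = c_max (1 − e^{−v/τ_e}) after v seconds of
  cumulative viewing: strictly increasing, concave, saturating — the
  empirical signature that viewing benefits plateau within about a
  second motivates the saturating-exponential family and the default
  τ_e = 0.75 s.
* **Decay.** c(v, d) = c(v) e^{−d/τ_d} after a retention delay of d
  seconds (default τ_d = 6 s). The decay *rate* is independent of the
  starting level, so log c(v, d) = log c(v) − d/τ_d is additive: the
  certainty surface has **zero interaction by construction**. This is
  the model's load-bearing premise; every interaction the analyses
  detect must come from the read-out, not the trace.
* **Free report.** The observer reads out ĉ = clamp(c + ε, 0, 1) with
  ε ~ N(0, σ) (default σ = 0.05) and acts only if ĉ ≥ θ (default
  θ = 0.25). An action succeeds with probability max(c, g), where
  g = 1/16 is the chance of hitting the right cell of a 4 × 4 grid by
  luck. For θ ∈ (0, 1] the closed form is
  P(placed) = Φ((c − θ)/σ) · max(c, g).
* **Forced report.** Report errors are von Mises with concentration
  κ = κ₀ · c(v, d) (default κ₀ = 20, giving single-item error SDs from
  ~60° at a 0.1 s glance down to ~14° after long viewing). The
  threshold never enters.

The saturating-exponential, exponential-decay, Gaussian-noise, and
clamp-then-threshold forms are modeling choices of this package, each
isolated behind one function so alternatives can be swapped. Whether
the noise lives in the trace or in the threshold is not identifiable
here; we place it in the trace.

`threshold_crossing_time` gives the geometry of the induced
interaction: a trace encoded for v seconds stays actionable for
t*(v) = τ_d ln(c(v)/θ), which grows with v — longer viewing delays the
moment performance collapses.

### Link scales in the dissociation experiment

`run_dissociation_experiment` simulates both paradigms from the same
certainty surface on a viewing × delay grid (default 0.5/1/2 s ×
1/3/6 s, chosen so every cell keeps placement probabilities inside
(0.01, 0.99) at the default parameters) and estimates each paradigm's
interaction on its natural link scale:

* free report — log-odds, via logistic regression of the binary
  placements on v, d, v·d;
* forced report — log concentration: per-cell von Mises κ is estimated
  by maximum likelihood and log κ̂ is regressed on v, d, v·d.

Log concentration is the scale on which the generative separability is
exact, so the forced-report interaction is zero in expectation on a
balanced grid regardless of the nonlinearity of κ(v, d) in raw seconds.
Confidence intervals are percentile bootstrap over trials within cells
(default 200 resamples).

Two curvature caveats, both documented rather than hidden:

* With the threshold removed (θ = 0), the free-report success
  probability equals max(c, g); because logit(c) of a multiplicative
  surface is not exactly additive, a small *negative* interaction
  (≈ −0.07 at defaults) survives on the logit scale. Removing the
  threshold removes the positive interaction; it does not produce an
  exact zero.
* Analogously, *linear*-scale precision (the conventional analysis of
  rigid tasks) inherits a small negative curvature term (≈ −0.09 at
  defaults) from the same separable surface. Interestingly, published
  estimates from rigid experiments tend to be small and negative with
  intervals near zero, which is what this artifact predicts. Tests
  therefore require the linear interaction to be small relative to the
  presentation-time main effect and require exact-scale nullity on
  log κ.

## Measure extraction

`vwmdyn.measures` implements the copying-task measures. A trial is an
ordered event stream (view_start / view_end / place plus optional
session markers). Sessions alternate viewing → building; explicit
markers are authoritative, and without them boundaries are inferred
from the stream (a viewing session spans a maximal run of views; the
following building session runs from the last view end to the next
run's first view start, or to the last placement for the final
session).

At the end of each building session, one row is emitted per item that
had been inspected and was unplaced at the session's start:

* **cumulative viewing time** — summed view durations up to the item's
  correct placement (views after placement are ignored);
* **delay** — from the end of the most recent view to the placement,
  or to the building-session end for unplaced items (right-censored);
* covariates: trial number, viewing-session index of the last view,
  and number of views.

The same physical item can appear in several rows across sessions.
Items are tracked by grid-cell identity, so identical-looking items in
different cells are distinct. Incorrect placements are outside the
event alphabet; only correct placements appear.

One discrepancy is deliberate: in the standard worked example of this
measure scheme (four views A–D, placements of B and C, building
session ending at t = 24.0 s), the censoring rule gives item D a delay
of 24.0 − 18.7 = 5.3 s, while the accompanying published table prints
6.5 s. The package follows the stated rule and flags the table entry
as inconsistent rather than reverse-engineering it.

`bin_performance` reproduces the binned performance curves (proportion
placed per viewing-time and/or delay bin, e.g. 3 × 3
short/medium/long); empty cells report n = 0 with a missing
proportion, and rows outside the bin span are excluded.

## Synthetic data

### Copying-task generator

`generate_copy_task_logs` emulates self-paced behavior per participant
and trial: viewing sessions inspect 1–4 items (uniform), single-view
durations are log-normal with median 0.5 s (σ_log = 0.6), views are
separated by 0.3 s gaps, and already-seen unplaced items are re-viewed
with probability 0.15 per slot. After viewing, every viewed-and-
unplaced item receives a placement decision from the free-report
process, in descending order of current certainty ("act on the highest
peak first"), each decision consuming a 1.5 s slot. Successes become
place events; failures leave no event. A building session is recorded
only when at least one placement succeeded — placement-free excursions
are unobservable in a correct-placements-only alphabet, so the viewing
session simply continues. This makes session boundaries exactly
recoverable from the view/placement stream alone, which the tests
exploit. Trials cap at 12 viewing sessions.

Participants differ by log-normal factors (σ = 0.2) on τ_e and τ_d.
One root seed spawns per-participant substreams, so identical configs
are byte-identical. With default parameters the emergent cohort
statistics — ≈ 6.5 viewing sessions and ≈ 1 minute per 8-item trial,
nearly all items eventually placed — sit in the realistic range for
this task family; they are emergent, not fitted.

What the generator does *not* emulate: interference from intervening
actions, output interference, deliberate rehearsal strategies, error
placements, or any perceptual/motor detail. Passing recovery tests
therefore show that the analysis pipeline is faithful to a
threshold-gated certainty process, not that human data contain no
other mechanisms.

### Rigid-task generator

`generate_rigid_task_data` mirrors a standard within-participant
continuous color-report design: presentation times 0.1/1.1/2.1 s ×
delays 2/4/6 s, 33 trials per cell, 60 participants, set size 1 or 3
between participants. Errors are von Mises with
κ = κ₀ · c(v, d) / set_size — log-additive in all three factors —
wrapped to (−180°, 180°]. Participants carry a log-normal factor
(σ = 0.4) on κ₀.

## Statistical layer

* `fit_logistic` — maximum-likelihood logistic regression (IRLS via
  statsmodels GLM) with the fixed-effect structure
  placed ~ viewing_time * delay + trial + viewing_session + n_views;
  covariates enter in raw seconds (slopes are per-second log-odds).
  Single-class outcomes and runaway coefficients (|β| > 15 on the
  logit scale, the quasi-separation flag) raise diagnostic errors;
  rank-deficient designs name the collinear terms. Optional
  participant-clustered sandwich standard errors.
* `likelihood_ratio_compare` — 2Δℓ with χ² reference, plus
  ΔBIC = BIC_reduced − BIC_full as a Schwarz-approximation surrogate
  for a Bayes factor. Per-participant random slopes are deliberately
  out of scope: fixed-effects ML plus the participant-cluster
  bootstrap (`cluster_bootstrap_ci`, percentile intervals, resampled
  participants relabeled as fresh clusters) carries the uncertainty
  instead.
* `precision_statistic` — 1/cSD (radians) minus its expectation under
  uniform responding at the same n. The chance term is seeded Monte
  Carlo (10,000 draws, cached per sample size, fixed internal seed
  1234), making the statistic deterministic in the data. cSD uses the
  resultant length: cSD = sqrt(−2 ln R); R below 1e-12 returns +∞.
* `fit_precision_model` — aggregates errors to one precision value per
  participant × condition cell (≥ 2 trials, undersized cells dropped
  with a warning). Within-participant terms are estimated on
  participant mean-centered precision; terms constant within every
  participant (a between-participants set size) come from a
  participant-level regression of mean precision, since centering
  would absorb them.

Tests are two-sided at α = 0.05 with no multiplicity correction (the
analysis style is model comparison, not families of tests).

## Numerical and design notes

* Time is continuous seconds from trial start; intervals are treated
  as half-open in construction, with closed boundary checks at shared
  timestamps (a placement may coincide with its session's end). Event
  ties serialize in a fixed order (view_end < place < session_end <
  session_start < view_start).
* Timestamps serialize with 3 decimals (lossless at monitor sampling
  rates); the event-log format is TSV, one event per line, with the
  session kind carried in the item column for marker lines.
* Logistic convergence follows statsmodels' IRLS defaults; the
  separation limit (15) is far beyond any plausible per-second
  log-odds in this domain.
* `run_demo` stamps `results.json` with the seed and a SHA-256 hash of
  the scientific configuration (output paths excluded), and is
  byte-identical under a fixed seed. Figures are advisory; all checks
  read tabular outputs.
* Problem sizes used by the shipped analyses (e.g., 3 × 3 × 500 trials
  for the dissociation, 10,000 Monte Carlo sets for the precision
  calibration, 1,000 simulations for type-I calibration) were chosen
  as the smallest sizes at which the targeted contrasts are stable
  desk-scale experiments.

## Known limitations

* The certainty model is one-dimensional: no feature binding, swap
  errors, or guess/memory mixtures beyond the single guess floor.
* ΔBIC is a crude Bayes-factor surrogate; it shares only the sign
  convention with bridge-sampling estimates.
* The generator's timing distributions (view durations, gaps, slot
  lengths, session policy) are plumbing defaults, not empirical
  claims; real single-view duration distributions are not published
  for this task family.
* Fitting the certainty model's parameters to real datasets is out of
  scope; the package simulates and analyzes, it does not estimate τ_e,
  τ_d, or θ from data.
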