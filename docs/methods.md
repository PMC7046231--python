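# Methods

This note documents the models, numerical choices, and open design decisions
behind `voa`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The assessment model

A trial is represented by k named metrics, z-scored against the training
cohort (sample standard deviation, n−1 denominator). The classifier is a
linear SVM: h(z) = θ·z + b with classes encoded skilled = +1 / novice = −1.
Sign rules are deliberately conservative for a mastery-learning context:
h = 0 classifies as novice, and a per-metric contribution θᵢzᵢ = 0 (the
trainee exactly at the cohort-mean benchmark) counts as *not yet* competent.
Ambiguity always fails toward more practice.

Expertise as a gradient uses the raw-margin logistic p(skilled) = σ(h) with
unit slope and zero offset. No Platt-style calibration is fitted: the
synthetic cohorts provide no calibration ground truth, and the sigmoid's
qualitative properties (monotone in h, 0.5 at the boundary, symmetric between
classes) are what the feedback display relies on. Numerically,
p(novice) = σ(−h) rather than 1 − σ(h), which makes the class-symmetry
identity p_skilled(−h) = p_novice(h) exact in floating point; the two
probabilities sum to 1 to within one ulp.

The bias enters h and the probabilities but is excluded from per-metric
verdicts — it is a weight without a corresponding metric. The decomposition
identity Σᵢ θᵢzᵢ + b = h holds exactly by construction and is property-tested.

## Training: iterative cost reduction

The trainer minimizes ½‖θ‖² + C Σᵢ max(0, 1 − yᵢ(θ·zᵢ + b)) by full-batch
subgradient descent with step size 1/t (the schedule for a 1-strongly-convex
objective), an unregularized bias, and a fixed iteration budget. Defaults:
C = 1.0, 1000 iterations (300 inside the selection search, which runs one
LOOCV per candidate subset). The solver is deterministic — no sampling, no
shuffling — so reproducibility needs no seed; the seed parameter is carried
into model provenance so stochastic variants and downstream resampling stay
reproducible. Subgradient descent is not monotone step-to-step; the tests
assert the objective falls from start to finish and that post-burn-in
excursions above the running minimum stay below 5% of the initial objective.
On separable data the trained direction agrees with an independently
implemented hinge-loss SVM (scikit-learn's `LinearSVC`, used in tests as a
cross-check only) in every training-set decision, with cosine similarity
above 0.95.

## Validation

Leave-one-out cross-validation refits the z-score normalization *and* the
classifier on each fold's n−1 members, so the held-out trial never leaks into
the statistics it is judged against (the package verifies this by fold-wise
recomputation with a corrupted held-out row). Sensitivity is defined on the
skilled class and specificity on the novice class, matching the convention
under which the original validation's 28/28 skilled correct reads as 100%
sensitivity. Reported rates are exact ratios; display rounding is one
decimal.

Metric selection is a wrapper search scored by LOOCV accuracy. Forward
phase: add the single best metric while accuracy strictly improves (ties to
the earliest candidate). Backward phase: drop any metric whose removal does
not decrease accuracy, preferring smaller sets. Phases alternate until a
full pass changes nothing; every evaluated subset and its accuracy is
recorded in the selection trace, and the final set's accuracy equals the
trace maximum by construction.

A known statistical limitation, measured with this package: with two
informative metrics at a 3 pooled-sd group gap among three noise metrics at
n = 30/30, the LOOCV accuracy estimate has granularity 1/60 and enough
variance that the estimated accuracy of the informative *pair* does not
always strictly beat the best single metric, even though its true accuracy
is higher. In repeated simulation the search recovers both informative
metrics in roughly 85–90% of seeds; the failures are estimator variance at
the Bayes boundary, not search defects (fold decisions match the independent
SVM exactly). Larger cohorts or wider gaps make recovery essentially
certain, as the deterministic diagonal-separation test shows.

## The synthetic-data generator

No raw recordings from the original task are public, so `voa.simdata`
generates them. The generator's purpose is controllable, analytically
tractable group separation on the four validated behaviours — not realism of
human neurosurgical motion (an explicit non-goal).

* **Base path** — constant-velocity drift from a random start. A drifting
  straight line contributes exactly zero acceleration, so the tremor
  parameter alone controls the acceleration metric.
* **Tremor** — per-axis white Gaussian acceleration with scale
  `tremor_accel_mm_s2`, passed through two leaky integrators (velocity
  damping τ = 0.1 s, displacement damping τ = 0.5 s). Undamped double
  integration would random-walk to metre-scale displacement over a 120 s
  trial and drown every positional metric; damping makes tremor a stationary
  jitter whose finite-difference acceleration scales linearly with the
  parameter and vanishes exactly at zero.
* **Tip separation** — the bipolar tip sits at a distance from the aspirator
  tip along a fixed random direction; the distance combines a per-trial level
  draw with a slow sinusoidal wander (0.02–0.08 Hz), both scaled by
  `tip_separation_sd_mm`.
* **Forces and bleeding** — a per-trial level drawn around the group mean
  plus per-sample Gaussian jitter, clipped at zero; bleeding is integrated to
  a non-decreasing cumulative volume starting at 0 mL.

Every scale parameter at zero collapses its channel to the analytic ideal
(constant force, exact separation, zero acceleration, linear accumulation),
which is what the closed-form metric oracles test. Units are fixed
package-wide as seconds, millimetres, newtons, millilitres; sampling defaults
to 20 Hz for 120 s (neither is dictated by the source platform, whose raw
channel list is unpublished — the CSV schema here is this package's own).
Per-member seeds use a stated affine rule,
`(cohort_seed·1000003 + 7919·index + 1) mod (2³¹−1)`, so a cohort is
reproducible from its spec in any language.

Default group profiles put the skilled group lower on all four behaviours
with moderate overlap (roughly 1.3–1.7 pooled sd per metric), chosen so the
default 28/22 cohort is about as hard to classify as a realistic skill cohort
— LOOCV accuracy typically in the high-80s to high-90s, with the wrapper
search keeping a multi-metric subset. What passing tests on these cohorts
shows is that the *pipeline* is correct and well-calibrated under known
separation; it does not show that real operators separate this way — the
generator models no tissue interaction, fatigue, learning within a trial, or
instrument-specific motion signatures.

## Metric numerics

* Acceleration uses the second divided difference over interior samples with
  per-interval Δt (exact on quadratics, endpoints dropped); a warning is
  raised if sampling intervals vary by more than 10%.
* Rate of bleeding is net volume over net time — the mean rate, not an
  instantaneous maximum.
* Max force is the instantaneous per-sample maximum; tip distance averages
  every sample with no idle-period trimming.

## Serialization

Models, selection traces, metric-table sidecars, and reports are
schema-versioned JSON (`voa-model/1` etc.); loading rejects version
mismatches and structural defects with a schema error. Python's JSON float
round-trip is exact, so save → load compares equal. The shipped
`reference_model.json` carries the published four-metric weights; its bias
and the source cohort's normalization statistics were never published, so
the fixture uses bias 0 and an identity normalization (inputs must already
be z-scored), as stated in its own metadata.

## Problem sizes

Stochastic checks run at the sizes the experiments module fixes: 10 seeds of
28/22 cohorts for separability, 20 label-permuted replicates of n = 40 for
the null, 10 seeds of n = 60 tables for selection recovery. These sizes keep
the whole suite around a minute while leaving the binomial bands meaningful.
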