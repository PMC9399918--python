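# Methods

This note documents the models, the numerical choices and the open design
decisions behind `ictonet`, and what the synthetic validation does and does
not establish about real recordings.

## Data model and preprocessing

A recording is a `channels × time` matrix at a fixed sample rate (1 kHz by
default) with an annotation giving stage onsets in seconds.  Timestamps
convert to sample indices by `floor(t · rate)`; stage epochs are half-open
`[start, end)` so adjacent stages share no sample.  Samples after the
annotated end are always dropped: the post-ictal interval is a refractory
period, not a stage.  Animals that never reach GTCS contribute 9-variable
tables (their GTCS variables are *absent*, not NaN-padded or imputed);
this propagates to the consensus through per-pair effective-K counting.

Stages are aligned by piecewise-linear interpolation onto the length of
the animal's *own* longest stage (not the cohort's), preserving endpoints
exactly.  Linear interpolation is the lowest-order scheme that preserves
monotone segments and introduces no overshoot; the alignment necessarily
distorts time within stages and induces strong autocorrelation in the
upsampled columns, which the downstream row-exchangeable likelihood simply
ignores — this is inherent to the table construction, not an artifact of
the implementation.

## Adaptive discretization

Each column is quantized independently with Knuth's Bayesian optimal
equal-width histogram: the bin count `M ∈ {1..128}` maximizes the marginal
posterior of a piecewise-constant density with Jeffreys priors,

    log p(M | x) = N ln M + lnΓ(M/2) − M lnΓ(½) − lnΓ(N + M/2)
                   + Σ_k lnΓ(n_k + ½)    (+ const).

The additive constant is dropped so that `log p(1 | x) = 0` exactly for
every dataset, which makes scores comparable across M.  Ties break toward
fewer bins.  A constant column has zero data range, where equal-width
binning with M > 1 is undefined; the objective is −∞ there and the column
quantizes to a single level.  Realized bins are relabeled to consecutive
integers so that unoccupied bins do not inflate BDeu parent-configuration
spaces.  The 128-bin cap is the protocol's stated resolution limit (7
bits); at the default validation scale the optimizer chooses ~30–80 bins,
well under the cap.

## BDeu scoring and search

The local score of child X with arity r and parent set of joint
cardinality q (product of full parent arities — required for score
equivalence) is

    Σ_j [lnΓ(α/q) − lnΓ(N_j + α/q)] + Σ_{j,k} [lnΓ(N_jk + α/(rq)) − lnΓ(α/(rq))]

with sparse counting over realized parent configurations only (unrealized
configurations contribute exactly zero), so 128-ary variables remain
tractable without a parent cap.  α defaults to 10, a common choice for
BDeu implementations; the study does not report its value.  The score is
decomposable and score-equivalent; both properties are exercised against
independent oracles in the test suite (a sequential Dirichlet-multinomial
predictive-product oracle, and exhaustive equivalence-class enumeration).

Hill climbing uses single-arc addition, deletion and reversal moves under
acyclicity and temporal precedence: arcs never point from a later stage to
an earlier one; intra-stage arcs are unconstrained; forward arcs of any
lag are allowed (the Markov-order bound is configurable but unbounded by
default, so the *absence* of a basal→GTCS dependence can be discovered
rather than imposed).  "One million iterations" is interpreted as a budget
of candidate-move score evaluations accumulated across random restarts;
each restart starts from a random DAG (uniformly random stage-consistent
topological order, each allowed arc included with probability 0.1) and
ascends greedily until no move improves the score by more than 1e-6; the
best DAG seen is returned.  Local scores are memoized by (child, parent
set).

**Tie-breaking is random (seeded), not lexicographic.**  Because BDeu is
score-equivalent, the two orientations of a new intra-stage arc are
usually an exact tie.  A deterministic lexicographic rule would make all K
replicate searches agree on one arbitrary alphabetical orientation,
collapsing precisely the replicate diversity that the model-averaging
threshold needs (the searches are *meant* to be non-deterministic).  Runs
remain exactly reproducible under a fixed seed.

## Consensus and the analytical threshold

For every unordered pair, forward/reverse/absent states are tallied over
the replicates containing both nodes; `forward + reverse + absent =
effective K` is asserted on every run.  An arc is accepted iff
`count / effective_K ≥ f(effective_K)` with `f(K) = 1/3 + 2/K` — strictly
above the 1/3 chance level of three equiprobable states, with a
finite-sample margin.  The comparison is `≥`, so a frequency exactly at
threshold passes; both directions are thresholded independently, and a
near-50/50 split at K = 21 (f ≈ 0.43) can legitimately accept both
directions of a pair, which is reported as bidirectional rather than
broken.  Note that for a GTCS-group pair (K = 11, f ≈ 0.52) bidirectional
acceptance is arithmetically impossible.

The stage-level projection draws an edge stage_i → stage_j when the chosen
arc set contains an inter-stage arc between them.  It defaults to the
*all-learned* arc set (accepted plus gray): the consensus table typically
retains no significant inter-stage arc, while stage-to-stage information
flow is a statement about the learned structures at large; the
accepted-only mode is also provided.

## Synthetic cohort

Within each stage, channels follow a first-order VAR
`x_t = A_s x_{t−1} + ε_t` (Gaussian innovations, spectral radius of every
`A_s` < 1 enforced); nonzero off-diagonal `a_ij` plants the ground-truth
arc channel_j → channel_i.  Cross-stage dependence is planted by mixing a
weighted, linearly resampled copy of an earlier stage's channel into a
later stage's channel, which is exactly the row-aligned dependence the
variable table can expose.  Defaults mirror the emulated study: 21
animals, 11 reaching GTCS; durations basal 120 s, infusion 300 s, MYO
60 s, GTCS 40 s with ±20 % uniform jitter at 1 kHz (≈3×10⁵-row tables at
full scale; the `scale` factor shrinks durations for experiments — tests
and the acceptance script use 0.05, i.e. ~13 000 rows); unit-variance
innovations; one independent RNG substream per animal spawned from the
master seed, so cohorts are byte-reproducible.

Two generator choices deserve justification:

* **Coupling strength is calibrated per stage, not uniform.**  The
  preictal pattern (TH→HP 0.3, TH↔CX 0.3, self-weight 0.65) reverberates
  through the TH↔CX loop and yields planted-pair correlations of ~0.7–0.8
  on its own; the acyclic GTCS chain CX→TH→HP does not, so it uses
  self-weight 0.85 and coupling 0.5 to plant dependence of comparable
  strength (~0.6–0.8).  Calibration was done directly on the VAR's
  stationary correlations, independent of the inference pipeline.
* **Carry-over runs through CX** (weight 0.6, chained
  basal→infusion→myo→gtcs, no basal→gtcs term).  The carry channel is the
  one channel that is never the sole driver of a direction-critical
  planted arc: adding a post-hoc carried component to TH dilutes the
  observed driver and manufactures spurious CX→HP dependence, while
  carrying through HP creates a two-parent collider whose CPT cost (two
  ~30-ary parents) BDeu refuses at this sample size, flipping the learned
  orientation.  With CX-carry, the collider-avoidance pressure from
  CX_prev→CX_s instead *aligns* the search with the planted orientations.

## What the validation shows — and what it cannot

On the study-sized cohort the pipeline recovers the planted intra-stage
arcs with high precision (1.0 at the default seed), finds the carry-over
chain, and reproduces the qualitative stage-graph finding (no basal→GTCS
edge).  Recall of the full planted arc set has a structural ceiling below
1: BDeu cannot distinguish Markov-equivalent orientations, each replicate
DAG can carry at most one direction of the planted TH↔CX two-cycle, and
the carry-over chain biases that choice toward CX→TH in the middle stages
— so the planted reverse arcs TH→CX there rarely reach the threshold
(observed intra-stage recall ≈ 0.73–0.82 across seeds).  This is a
property of the method being emulated, not a bug; a consensus of
score-equivalent searches identifies skeletons and compelled orientations,
and the analytical threshold is designed to reject directions that are
orientation-noise.

The simulator is linear, Gaussian and stage-stationary, with no 1/f
spectral shaping, volume conduction, artifacts or nonstationarity within
stages.  Passing recovery tests therefore demonstrates the correctness of
the pipeline's machinery on data satisfying its assumptions — it does not
certify performance on real LFP, whose nonlinear and nonstationary
structure is exactly what motivates the nonparametric discrete approach.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| sample rate | 1000 Hz | digitization rate of the protocol |
| max bins | 128 | 7-bit cap on per-column quantization levels |
| ESS α | 10 | BDeu prior equivalent sample size |
| max iterations | 10⁶ | candidate-move evaluations across restarts |
| max parents | unbounded | sparse counting keeps scoring tractable |
| init arc prob. | 0.1 | density of random restart DAGs |
| f(K) | 1/3 + 2/K | consensus acceptance threshold |
| K / GTCS fraction | 21 / 11⁄21 | cohort size and group split |
| noise σ | 1.0 | VAR innovation scale (arbitrary LFP units) |
| carry-over | CX→CX, 0.6 | adjacent-stage mixing weight |
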