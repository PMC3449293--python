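# Methods

## The scientific question

In conflict tasks such as the flanker paradigm, interference (slower, less
accurate responses to incongruent stimuli) shrinks for stimuli shown in a
context — here, the side of fixation — where incongruent trials are
frequent. This context-specific proportion congruent (CSPC) effect admits
two mechanistic readings: contexts may prime *processing selectivity*
(faster evidence accumulation about the target under frequent conflict), or
they may prime *response caution* (more evidence demanded for contextually
unexpected stimuli). Mean RT cannot separate these; a process model of
choice and RT distributions can, because drift-rate changes and threshold
changes leave different signatures on the joint distribution of accuracy
and RT.

## The model

Each two-choice decision is a race between two linear ballistic
accumulators (LBA). Accumulator *i* starts at a point drawn uniformly from
[0, A], accumulates at a rate drawn once per trial from Normal(v_i, s), and
responds on reaching threshold b. Observed RT is the winner's hit time plus
a non-decision time t0. The single-accumulator hitting-time CDF is

    F(t) = 1 + ((b−A−tv)/A)·Φ(z1) − ((b−tv)/A)·Φ(z2) + (ts/A)·(φ(z1) − φ(z2)),
    z1 = (b−A−tv)/(ts),  z2 = (b−tv)/(ts),

with pdf f(t) = (1/A)·[−v·Φ(z1) + s·φ(z1) + v·Φ(z2) − s·φ(z2)]. The joint
density of responding with a given choice at time t is the *defective*
density f_choice(t−t0)·(1−F_other(t−t0)); it integrates to that choice's
probability. A drift draw ≤ 0 never finishes, so the defective densities
jointly integrate to 1 − P(both drifts ≤ 0). At the parameter scales of
flanker data this deficit is below 1e−5; no renormalization is applied, and
the simulator redraws such trials.

Conventions and numerical choices:

- **Error drift.** The data constrain one drift per condition; the error
  accumulator's mean is 1 − v. This sum-to-one convention fixes the scale
  and makes v identifiable alongside a free s.
- **Shared nuisance.** Both accumulators share b, A, s within a condition
  (no response bias); s, A and t0 are constant across all conditions in
  every model.
- **A → 0 branch.** Below A = 1e−8 the closed form is replaced by its limit
  F(t) = Φ((v − b/t)/s), f(t) = (b/t²)·φ((b/t − v)/s)/s. The exact CDF
  deviates from this limit by O(A), so the switch is continuous to ~2e−8.
- **Guards.** The t·s terms are floored at 1e−10; the defective density is
  floored at 1e−10 before logs so the likelihood is finite everywhere
  inside the optimizer's box, and F(t) = 0 for t ≤ 0.
- **Units.** Seconds internally; RTs in ms are divided by 1000 at ingest.

## Model space

Four conditions (context: low/high conflict × congruency). Thresholds are
parameterized as distances d = b − A > 0, so box bounds enforce b ≥ A.

| model | k | free parameters besides s, A, t0 |
|-------|---|----------------------------------|
| V1 | 8 | one d; v per condition (4) |
| V2 | 7 | one d; v_CL, v_IL, Δv with v_IH = v_IL + Δv, v_CH = v_CL − Δv |
| B1 | 9 | d per condition (4); v per congruency (2) |
| B2 | 8 | d_CL, d_IL, Δb with d_IH = d_IL − Δb, d_CH = d_CL + Δb; v_C, v_I |
| VB | 11 | d and v per condition (extension) |
| T0 | 8 | one d; v_C, v_I; t0_CL, t0_IL, Δt0 (extension) |

Positive Δv/Δb produce the standard CSPC direction. The published verbal
description of B2 ("the reduction in thresholds for incongruent stimuli
matches the increase for congruent ones") conflicts with the accompanying
formula line, whose subscripts would base both high-context thresholds on
the incongruent-low distance and give the opposite sign convention. The
verbal reading is implemented because only it makes positive Δb produce
standard CSPC effects; the literal reading is available via
`build_condition_params(..., b2_literal=True)`. Whether the drift models
share a single b or a single d is not documented; a single d is used. VB
and T0 are provided for recovery completeness and excluded from the
headline four-model comparison.

## Fitting

Per-participant maximum likelihood: the objective is the summed log
defective density over all responded trials (omissions removed; no RT
trimming for fitting, so 408–448 trials per participant). The search is a
constriction-type particle swarm (inertia 0.72, cognitive = social = 1.49,
velocity clamped to half the box range) over box bounds s, A, d ∈
(0.001, 2], v ∈ [0, 2], Δv, Δb ∈ [−1, 1], t0 ∈ (0.01, min RT − 5 ms),
with seeded restarts. The first restart includes a moment-based start
particle (t0 ≈ 0.85·min RT, d from mean decision time). Every restart's
best point is polished with bounded Nelder-Mead; polishing per restart
rather than once guards against a swarm that stalls outside its basin's
optimum. All draws come from one seeded generator, so refits are
bit-reproducible. Default budget is 30 particles × 150 iterations × 2
restarts; recovery *scoring* uses 40 × 300 × 3, because residual optimizer
noise would otherwise contaminate the estimator's measured error.

AIC = 2k − 2 ln L̂ and BIC = k ln N − 2 ln L̂, with N the trial count
entering the likelihood; hence BIC − AIC = k(ln N − 2), and BIC penalizes
more whenever ln N > 2 (N ≥ 8) — at N ≈ 445 the BIC penalty per parameter
is ln(445)/2 ≈ 3.05 in log-likelihood units. ΔIC weights are
exp(−ΔIC/2), normalized. The threshold-vs-drift evidence ratio is
(w_B1 + w_B2)/(w_V1 + w_V2). Ties in best-model tallies (ΔIC = 0 for
several models) are split equally. The mean evidence ratio across data
sets is the unweighted arithmetic mean of the per-data-set ratios
(computed from per-data-set mean weights), which is the aggregation that
reproduces the published summary values.

## Behavioral descriptives

Conventional statistics use the stricter trimming: first trial of each
block, RTs outside [150, 2000] ms, and omissions removed; RT means
additionally exclude post-error correct trials (accuracy keeps them).
Post-error and context-transition labels are defined relative to the
previous *retained* trial within a block (the alternative — pre-trim
adjacency — is not documented in the source analyses; retained-trial
adjacency was chosen because it is idempotent under re-trimming). The CSPC
statistic is (I − C)_low − (I − C)_high in ms (or percentage points for
errors). Inferential ANOVAs are out of scope by design; the module exposes
the cell means and contrasts such tests are built on.

## Synthetic cohorts

The generator reproduces the study design exactly, not in expectation: 448
trials (4 × 112 scanner design or 7 × 64 behavioral design), equal trials
per side, 75% incongruent on the high-conflict side and 75% congruent on
the other, realized by counterbalanced allocation then a seeded shuffle.
Target direction is balanced at random and defines spatial S-R
compatibility labels. Omissions are injected at 0.7% (matching a mean of
~445 valid trials of 448). Randomness flows from a master seed through
per-participant spawned streams.

Default generating values are the published group-average B2 parameters
per data set, which place simulated cohorts in the observed regime
(~93–94% correct, grand-mean RT ~700–760 ms for the scanner design,
interference ~100–130 ms, CSPC ≈ +25–30 ms at Δb = 0.01). One regime
difference is worth noting: under pure threshold generation the error-rate
CSPC contrast comes out slightly *negative* (raised thresholds cut errors
as well as speed), whereas observed data show a positive error-rate CSPC —
a reminder that the group-average B2 point is a summary, not a full account
of every observed contrast. The generator
simulates homogeneous participants at those group means; real data have
between-participant parameter variability, slow drifts in attention,
sequential effects beyond context transitions, and contaminant RTs, none
of which are emulated. Passing recovery tests therefore demonstrates
identifiability and correctness of the machinery under the design's trial
counts — not that real participants satisfy LBA assumptions.

## What recovery can and cannot show at these effect sizes

With 448 trials and the published effect size Δb = 0.01, the expected
log-likelihood advantage of the generating B2 model over its V2 rival is
≈ 3.1 per participant (measured by refitting a 17,920-trial simulated
participant), while BIC's penalty for B2's extra parameter is ≈ 3.05.
B2-vs-V2 selection by BIC is therefore almost exactly at its penalty
boundary: per-participant BIC class recovery from B2-generated data hovers
near chance, whereas AIC (penalty 1.0 per parameter in the same units)
recovers the threshold class clearly, and drift-generated data are
recovered by both criteria. This is a property of the design and effect
size, not of the optimizer; it is consistent with the published pattern in
which the BIC evidence ratio (1.87) is much weaker than the AIC ratio
(~4). Parameter recovery is unaffected: drift rates come back with median
absolute error < 0.05 and the sign of Δb is recovered in ~90% of
simulated participants.

## Problem sizes used by the test suite and acceptance script

Density oracles use 10⁶ Monte-Carlo draws (3-SE bands) and 10⁵-point
quadrature; simulator consistency uses Kolmogorov–Smirnov distance < 0.01
at n = 10⁵; model-implied quantile checks use 2 × 10⁶ simulated trials so
that the 5 ms agreement band exceeds the Monte-Carlo noise of the sparse
error class. Recovery studies use 20 simulated participants × 448 trials;
the four-model sweeps run at the reduced swarm budget (equal across
models), parameter-recovery scoring at the convergence-grade budget.
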