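# Methods

`multidec` models behavior in tasks where an observer makes *two*
binary perceptual decisions about one object — for example the dominant
color and the net motion direction of a single patch of dynamic random
dots — and asks whether the two decisions are formed in parallel or one
at a time.  This note documents the models, the numerical choices, and
what the synthetic-data generators do and do not emulate.

## 1. One-dimensional bounded drift-diffusion (`ddm_core`)

Each stimulus dimension x ∈ {motion, color} drives an independent
accumulator

    dV_x = μ_x dt + dW,     μ_x = κ_x (s_x + s_x0),

with unit diffusion variance per second (so Var[V] = 1 after 1 s of
unbounded accumulation; this scaling convention costs no generality).
`s_x` is the signed coherence (positive = rightward / blue), κ_x a
sensitivity, and s_x0 a bias expressed as a coherence offset.  The
decision terminates at the first crossing of a symmetric bound ±B(t).
Two bound families are supported:

* logistic collapse `B(t) = u / (1 + exp(a (t − d)))` — equals u/2 at
  t = d; collapsing bounds produce slower errors;
* clipped exponential `B(t) = u · min(2^−(t−g)/d, 1)` — flat at u until
  t = g, then decays with half-life d (used by the variable-duration
  model).

First-passage sub-densities are obtained by solving the Fokker–Planck
equation with a Crank–Nicolson scheme on a fixed evidence grid spanning
[−u, u], Dirichlet (absorbing) conditions at the grid ends, and per-step
absorption of any mass at or beyond the instantaneous bound.  The first
four steps are taken as pairs of fully implicit half-steps (Rannacher
start-up) to damp the oscillations Crank–Nicolson exhibits with a delta
initial condition.  Mass lost at the walls in a step is split between
the upper and lower bound in proportion to the near-wall density, which
is proportional to the outgoing flux at an absorbing wall.  Probability
bookkeeping is exact by construction: absorbed mass + survivor mass = 1
to machine precision at every step, and the solver raises if this or
positivity fails beyond 1e−6.

Defaults: dt = 0.5 ms, horizon 5 s (the task response deadline),
512 grid nodes.  At these settings the flat-bound closed forms —
P(upper) = 1/(1 + e^{−2μB}) and the driftless mean first-passage time
B² — are reproduced to better than 1e−3, and refining dt and the grid
2× moves the choice probability by under 1e−3.  Fitting routines use a
coarser configuration (dt = 5 ms, 96 nodes), inside the convergence
envelope for the smooth quantities they need.

For experimenter-controlled durations, the probability of a positive
choice is the absorbed upper mass up to the duration plus the positive
unabsorbed mass at the duration; mass exactly at V = 0 (possible only
when the grid has a zero node) is split 50/50 — unbiased, symmetric,
and measure-zero in the continuum.

## 2. Double-decision composition (`combine`)

Let f_x(t | R_x) be the sub-density of dimension x terminating at t
with choice R_x.  For the four choice pairs (R_m, R_c):

* serial rule: decision time T = T_m + T_c; density = convolution of the
  two sub-densities;
* parallel rule: T = max(T_m, T_c); density = f_m F_c + f_c F_m
  (ended-at-t × other-ended-before-t), numerically identical to the
  derivative of the product of the sub-CDFs.

Both rules leave the marginal choice probabilities untouched — neither
predicts accuracy interference — but they differ in RT structure:
hardening one dimension shifts the serial mean-RT family uniformly
("stacked" curves) while the parallel family pinches where the other
dimension is weak.  Convolutions are computed by FFT on the shared
solver grid (zero-padded to avoid wrap-around); tail mass beyond the
horizon is reported by `RTDensity.tail_mass_deficit`.

Non-decision time is normal with mean μ_nd and SD σ_nd, truncated at
zero and renormalized (RTs must be positive; the truncation is
negligible for realistic parameters).

## 3. Likelihood fitting and model comparison (`fit_compare`)

The double-decision likelihood is over (R_m, R_c, RT) triples: composed
densities are evaluated at each trial's RT by linear interpolation on
the grid, floored at 1e−10; RTs beyond the horizon contribute the
model's beyond-horizon tail mass for that condition.  Both rules carry
12 parameters (κ, s0, u, a, d per dimension, plus μ_nd, σ_nd), so
models are compared directly by likelihood, summarized as
log10 BF = (LL_serial − LL_parallel)/ln 10 — positive favors serial.
The fit-on-strongest protocol fits on the conditions where at least one
dimension is at its maximum strength (32 of 81 conditions in a 9×9
signed design; 40 of 121 in an 11×11) and evaluates the held-out
likelihood of the rest.

Optimization is multi-start Nelder–Mead within parameter bounds
(default 8 starts: one heuristic plus seeded uniform draws).  Zero-
coherence trials are always included in fits; "correct" bookkeeping for
summaries treats either choice as correct at zero coherence.

The logistic interaction analyses ask whether the strength of one
dimension modulates sensitivity to the other: nested logistic models
with and without an s·|s_other| interaction (or a task-type interaction
with subject indicators for single-vs-double comparisons), compared by
BIC with the convention ΔBIC = BIC(full) − BIC(reduced), positive
supporting the no-interaction model.  On (quasi-)separation the fit
falls back to a weak L2 penalty and flags the result.

## 4. Empirical gamma decomposition (`empirical_rt`)

A complementary, diffusion-free analysis: the observed 2D RT
distributions are explained by latent gamma decision-time distributions,
one per (signed coherence, choice) cell of each dimension, combined
under the serial or parallel rule and convolved with a per-choice-pair
gamma non-decision time.  Only strengths × choices cells with more than
10 trials enter.  Gammas are parameterized by mean and SD (a bijection
to shape/scale).  Densities are composed on a shared grid (dt = 5 ms,
horizon auto-sized to the slowest trial) with an FFT cache across
optimizer evaluations.

Optimization is bounded L-BFGS-B on the log means and log SDs from a
moment-based initialization.  (A quasi-random global search is futile
in the ~30-dimensional cell space; the likelihood is smooth in the log
parameters and local ascent from moments converges reliably.)  A pooled
variant for the same/different task uses unsigned strengths, correct
trials only, and a single non-decision gamma.

Identifiability note: with a single difficulty level per dimension, the
serial and parallel compositions can mimic each other exactly by
repartitioning the latent means, so rule comparison requires at least
two difficulty levels per dimension sharing latent cells across
conditions.  The recovery harnesses use an easy+hard 4×4 signed design.

## 5. Variable-duration buffer model (`duration_buffer`)

For experimenter-controlled durations, both dimensions are acquired in
parallel for a buffer capacity T_buf, then processed serially with
motion prioritized with probability p_m1st.  The prioritized dimension
integrates for the full stimulus; the other dimension's available time
is: the full duration if the stimulus is shorter than the buffer or the
prioritized decision ended inside the buffer window; the buffer plus
the post-termination remainder if it ended later; the buffer alone if
it never ended.  T_buf = 0 is purely serial; T_buf at or above the
longest duration is effectively parallel.  Choices only are modeled
(no non-decision parameter), with clipped-exponential bounds.

The choice-pair likelihood integrates over the prioritized dimension's
absorption density (and survivor mass) to set the other dimension's
processing time, mixing over prioritization.  T_buf is profiled on the
protocol grid (40 ms steps to 240 ms, then 120 ms steps to 1200 ms),
refitting the remaining 11 parameters at each grid value by Nelder–Mead
from a common starting point, plus a short continuation run from the
neighboring grid point's optimum to keep the profile smooth; no grid
value is favored by initialization.

## 6. Multi-switch model (`multiswitch`)

In the bimanual task each dimension is reported as soon as it resolves,
giving two RTs per trial.  With the base serial fit (to the second
response and choices) fixed, three parameters shape the first response:
the switch-interval scale τΔ (intervals are the max of two exponentials
with mean τΔ, so E[interval] = 1.5 τΔ — a single-peaked density that
suppresses very short intervals), the starting-dimension probability
p_m1st, and the first-report non-decision mean Tnd1st.  During an epoch
only the active dimension accrues evidence; absorption interrupts the
epoch in progress, and after the first absorption the survivor runs
uninterrupted.  Clock time always advances, so the second response time
(= T_m + T_c + Tnd) is independent of the three parameters by
construction; the first report is additionally clipped to not follow
the second.  The single-switch observer is the τΔ → ∞ limit, detected
when the fitted τΔ reaches its search bound (20 s).

Fitting minimizes the summed squared error of mean first-response times
over four groupings (reported-first dimension × own/other strength),
with common random numbers: the evidence-time absorptions are drawn
once (they do not depend on the three parameters) and each candidate
re-runs only the seeded schedule overlay, making the objective
deterministic and cheap.  Simulation-based SSE is used instead of
likelihood because trial-level likelihoods of continuous RTs are
unreliable from finite simulations.

## 7. Same/different model (`samediff`)

Two patches drive two up/down diffusions with flat bounds and a shared
sensitivity and up/down bias; the binary report is "same" iff the two
direction decisions agree.  The 1D (single patch) and 2D tasks are fit
jointly with task-specific bounds and non-decision means.  The 2D
decision time is the sum (serial) or max (parallel) of the two patch
decision times; correct-trial means neglect double errors.  For flat
symmetric bounds the decision-time distribution conditioned on either
choice has the same shape, which the predictions exploit.  The joint
objective is binomial in the choices and Gaussian in the per-cell mean
RTs with standard errors taken from the data (no extra variance
weights).  Flat bounds underestimate error RTs; error-trial RTs are
excluded from the fit surface.

## 8. Stimulus generation and reverse correlation (`stimulus_revcorr`)

Dots are replotted each frame at 75 Hz in a square field; a dot shown
on frame n reappears on frame n+3 (40 ms) displaced by speed × 40 ms
with probability |motion coherence| (sign = direction), otherwise at a
random location; colors are iid Bernoulli with
p_blue = color coherence/2 + 1/2.  Dot count per frame is
density × area / frame rate.

Motion energy uses a parameterized opponent quadrature filter bank:
even/odd spatial Gabors × fast/slow temporal kernels t^n e^{−t/τ},
combined into direction-selective pairs, squared, summed, and pooled
over space (the dot field is pooled over y first).  The temporal
impulse response spans roughly 100–150 ms, so energy traces outlast a
120 ms pulse.  The color signal is the per-frame blue-minus-yellow
count convolved with the same impulse response.  The filters are a
configurable stand-in for physiologically derived kernels: their
spatial and temporal constants are free parameters, and the spatial
pooling nonlinearity (squared quadrature sum) is one of several
reasonable choices.

For reverse correlation, single-trial energy traces are detrended by
the mean over all trials with the same signed coherence (an exact
within-group identity) and averaged conditional on choice; residual
averages are invariant to any coherence-dependent offset.  Groups with
fewer than 2 trials are excluded.

## 9. Synthetic data (`synthetic_data`) — what it does and does not emulate

Trial generators use Euler–Maruyama accumulators (step 0.25 ms by
default, finer than the solver grid, cross-validated against the solver
within binomial error) under four architectures: serial (RT = T_m +
T_c + Tnd), parallel (max), multiswitch (renewal alternation, two
report times), and buffer (fixed-duration choices).  Design presets
cover the 9×9 and 11×11 signed factorial free-response designs, the
120 ms brief-presentation design, and the 6×6 × 10-duration variable-
duration design with rare easy-easy cells (~2.4% of trials).  A
censoring horizon of 5 s matches the task deadline; censored trials are
flagged, never dropped.  Seeded runs are byte-identical.

The generators emulate the *structure* of the behavioral data (designs,
architectures, RT composition, prioritization, switching), not the full
richness of human data: no session/learning effects, no lapses or
fixation breaks, no cross-dimension non-decision correlations, no
coherence-dependent diffusion variance (the constant-variance
assumption is restrictive and is shared by the fitted models), and
stimulus generation is decoupled from the accumulators except in the
closed-loop reverse-correlation checks.  Passing recovery tests
therefore demonstrates internal consistency of estimator and model —
not that human data obey these models.

The deterministic bottleneck timeline (`bottleneck_timeline`) encodes
the conceptual sample/buffer/update schedule: buffers sample no faster
than every τs (first sample at τs, samples available for about one τs
past stimulus offset), clearance issues an update instruction taking
τins with only one instruction in flight, and clearance alternates
among dimensions holding a sample.  With τs = τins = 90 ms and motion
first, the motion decision variable first updates at 180 ms and color
at 270 ms; during alternation each dimension's update interval doubles
relative to solo processing.  τv (40 ms) annotates the decision-circuit
time constant but is not rendered as continuous dynamics.

## 10. Validation harnesses (`validation`) and problem sizes

Desk-scale study conditions, chosen once for identifiability:

* rule recovery (diffusion and gamma): 20 datasets per generating rule,
  easy+hard 4×4 signed design, 2304 trials per dataset (the
  free-response session count of the reaching task); both candidate
  rules are refit warm-started from the same generating values, so
  initialization favors neither; selection by (log10) likelihood ratio;
* κ recovery: 10⁴ serial trials, κ_m = 10, κ_c = 12, slowly collapsing
  bounds, cold multi-start fits;
* buffer capacity: ~3000 fixed-duration choice trials per simulation at
  the 80 ms validation capacity with strong color sensitivity
  (κ_c = 30) and hard motion levels that frequently terminate inside
  the serial phase — the regime in which the capacity both caps and
  shifts the color allocation, making it identifiable; the profile over
  0–240 ms (40 ms steps) is summed over a few independent seeded
  simulations, mirroring a validation protocol that repeats the
  simulation rather than enlarging one dataset;
* multi-switch: τΔ = 0.47 s (mean interval ≈ 0.7 s), p_m1st = 0.8,
  Tnd1st = 0.3 s, 250 simulated trials per condition on a 3×3-level
  bimanual design.

At these sizes the profile of the buffer capacity is shallow on the
likelihood scale (a few nats between neighboring 40 ms grid values), so
the capacity estimate carries sampling variability of about one grid
step; the recovery harness conditions were chosen to keep the argmax at
the generating value with high probability.

## 11. Known limitations

* The Fokker–Planck flux split at the walls is first-order accurate;
  sub-1e−3 agreement with closed forms is demonstrated at the default
  grid, not guaranteed for exotic configurations.
* Nelder–Mead refits with capped evaluations trade optimality for
  runtime; the contract is that recovered quantities meet their stated
  tolerances, not that every fit reaches the global optimum.
* The empirical gamma decomposition is only rule-identifiable with
  multiple difficulty levels (see §4).
* The motion-energy filters are a parameterized stand-in; absolute
  energy units are arbitrary and only contrasts/residuals are
  interpretable.
* The buffer model fits choices only; it makes no RT predictions for
  the variable-duration task.
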