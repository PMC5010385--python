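# Methods

This note documents the models implemented in `memtag`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open. Notation: trial index `n` runs 1..88 over the test period;
forces are in newtons with rightward positive; x is rightward, y points
from the start position to the target 0.10 m ahead.

## The experimental design being modeled

A participant performs 373 reaching trials: 20 baseline trials (12 of them
error-clamp), 12 training blocks of 22 trials (trials 1–2 and 21–22 of
each block are error-clamp trials covering the 6 s stimulation ramps, the
middle 18 are force-field trials), one error-clamp trial without
stimulation after the mid-training rest, and 4 test blocks of 22 trials,
all error-clamp. Field direction and stimulation polarity alternate every
block and are yoked (rightward↔anodal by default; reversed for the
`Tffrev-T` group). In the test period polarity alternates with no field;
the ACAC subgroup starts anodal, CACA starts cathodal. `S-T` delivers sham
during training, `T-S` sham during test; `PPC` shares the `T-T` schedule
(the stimulation site differs, which the schedule does not encode).

Design choices where the protocol leaves freedom:

* **Baseline clamp placement.** Which 12 of the 20 baseline trials are
  clamp trials has no analysis consequence; a fixed deterministic
  interleaving (trial index mod 5 ∈ {1,2,3}) is used.
* **Rest trial.** The single no-stimulation clamp trial between training
  blocks 8 and 9 is its own phase (`rest_clamp`) so phase counts reconcile
  to 373 (20 + 264 + 1 + 88).
* **Stimulation timing.** The inter-trial interval is 6 s, so a 22-trial
  block spans 132 s; ramps overlap the first/last clamp trials (the target
  appears when the current passes ±1 mA). `stim_current` implements the
  per-block profile; the two transition clamp trials are not tied to exact
  ramp sample times anywhere in the analyses.
* **Practice trials** (40, null field, no stimulation) carry no analysis
  role and are excluded from the schedule.

## Synthetic test-period force

```
F(n) = A1 exp(B1 n) + A2 exp(B2 n) + C + polarity_sign · s(n) · m/2 + ε(n)
```

with `s(n)` = +1 under cathodal, −1 under anodal, 0 under sham/off
stimulation, and `ε ~ N(0, σ_trial²)` i.i.d. across trials. Defaults:
`A1 = −1.5 N, B1 = −0.15 /trial` (fast component), `A2 = −0.5 N,
B2 = −0.01 /trial` (slow component), `C = 0`, modulation `m = 0.7 N`
peak-to-peak, `σ_trial = 0.3 N`. The modulation amplitude is chosen so the
polarity effect is roughly 7–10 % of the ±4 N full-adaptation range
(viscosity 10 N/(m/s) × 0.4 m/s peak velocity) — the scale of effect the
paradigm is designed to detect. Between-subject variation
(`σ_subject = 0.2 N`) perturbs the amplitudes A1, A2, C and m only, never
the rates, keeping each 88-trial per-participant fit well-posed. A
per-participant constant offset (`baseline_offset_sd = 0.1 N`) is added to
every clamp force and must be removed by baseline subtraction — a check
that the preprocessing stage is actually wired in.

`polarity_sign` (default +1: cathodal drives force positive/rightward)
exists because the defining equation of ΔForce and the verbal description
of its expected sign in this literature can be read with opposite
orientations; rather than silently resolving that, both the generator's
sign and the ΔForce orientation are explicit parameters. Under the
defaults the closed-form expectations are `E[ΔForce_b] =
polarity_sign·m·(+1,−1,+1,−1)` over the four test blocks, hence
`E[BO] = −4·polarity_sign·m`.

The Gaussian, independent trial noise is an explicit simplification: real
trial series show autocorrelation, drifts and occasional outliers. The
generator also makes the square wave instantaneous at block boundaries,
while physiological polarity effects presumably ramp with the current.
Passing tests therefore certify the statistical machinery under the
design's assumed structure, not robustness to violations of it.

## Synthetic training behavior

A context-gated two-state learner: memory states `x_R, x_L` (one per field
context) plus a shared state `x_S`, in signed units of full compensation.
On a field trial in context c the motor output is
`o = γ·x_c + (1−γ)·x_S`, the error is `e = ideal(c) − o` (ideal = ±1), and
the update routes the error by the same gate after retention:
`x_c ← a·x_c + γ·b·e`, `x_S ← a·x_S + (1−γ)·b·e`. Lateral deviation on a
field trial is `dev_scale · e` plus noise; clamp trials read out
`−o · (k·v_peak)`. Defaults: retention `a = 0.9`, learning rate `b = 0.3`,
gating `γ = 0.5`, `dev_scale = 18 mm` per unit of uncompensated field,
`σ_dev = 2 mm` — values producing first-trial deviations of a few
centimeters that shrink within blocks, the qualitative pattern of curl-field
adaptation. γ = 1 yields fully separate memories (small first-trial
deviations in late blocks); γ = 0 yields one interfering memory (persistently
large first-trial deviations). The learner is deliberately phenomenological:
it generates the interference-versus-separation contrast the
training-period ANOVA must detect, nothing more.

## Kinematic traces

Reaches follow a minimum-jerk profile over 0.10 m,
`y(τ) = d(10τ³ − 15τ⁴ + 6τ⁵)`, whose peak velocity is
`v_peak = 1.875·d/T`; the sampling grid is centered on the velocity peak so
the requested `v_peak` is attained exactly at a sample. Clamp-trial lateral
force and field-trial lateral deviation follow a velocity-shaped bell whose
value at peak velocity equals the requested per-trial metric, so the
simulate → filter → differentiate → read-at-peak round trip must return the
injected value (tested to 1e-3 N on noiseless traces).

## Preprocessing

4th-order Butterworth low-pass at 10 Hz applied forward-backward
(zero-phase; the magnitude response is squared, DC gain exactly 1) on the
1 kHz channels; the order and the zero-phase application are standard
kinematic practice and are config-exposed (`FilterSpec`). Velocity by
central differences (one-sided at the ends). "Peak velocity" is read as
peak *speed* (vector norm); a flag switches to |vy| — which of the two the
original analysis used is not decidable from its description, and for
essentially straight y-directed reaches they coincide. Baseline
subtraction removes the per-participant *mean* of the 12 baseline clamp
forces (and of the baseline deviations); mean rather than median, in the
absence of any statement to the contrary.

## Model-free analysis

ΔForce is the trialwise difference of subgroup mean forces,
`ΔForce = F̄_CACA − F̄_ACAC` by default (`orientation` flips it). Because
both subgroups share the training protocol, the common memory decay
cancels and a polarity-locked effect survives as a square wave. Block
means average all 22 test-period clamp trials of each block (no transition
trials are excluded in the test period). Bootstrap bands resample
participants with replacement independently within each subgroup
(default N = 10,000).

Permutation tests relabel participants into two pseudo-subgroups of the
original sizes without replacement, recomputing the contrast each time
(default N = 10,000); with ≤ 12 participants all C(n, n₁) assignments are
enumerated exactly. Between-group tests reassign participants across
groups while retaining subgroup labels (stratified relabeling). The
p-value is the fraction of the null at least as extreme as the observed
value; sampled tests use the (count+1)/(N+1) finite-sample correction
(valid test, p > 0 guaranteed; the raw proportion is available via
`correction=False`). Sidedness defaults to two-sided — "more extreme" is
directionally ambiguous and the predicted direction differs per contrast —
with one-sided options exposed.

## Model-based analysis

Per participant, `y = A1 exp(B1 n) + A2 exp(B2 n) + C` is fitted to the 88
test-period forces by variable projection: nonlinear least squares over
the rates only (bounded to [−5, 0]), amplitudes solved by linear least
squares at every step, started from a deterministic grid of rate pairs
(−1, −0.3, −0.1, −0.03, −0.01; the four best by profiled SSE are refined;
tolerances 1e-10). Labels are canonicalized to |B1| ≥ |B2|. Degenerate
constant series return amplitudes 0 and C equal to the constant. The
single-exponential variant guards against the double fit's extra
flexibility manufacturing residual structure; nesting (double SSE ≤ single
SSE) is enforced by test. Non-negative-rate solutions are excluded by the
bounds — growth is not a decay model — and a participant whose fit fails
from every start would be excluded with a log entry.

Blockwise residual means feed a balanced mixed repeated-measures ANOVA.
Sums of squares are computed by inclusion–exclusion over marginal means
(exact for balanced designs); between-subject effects are tested against
the subjects-within-groups stratum, and every within effect (and its
interactions with between factors) against the corresponding
subject × within-term stratum. ηp² = SS_effect/(SS_effect + SS_error).
Sphericity corrections are not applied: all within factors in the
test-period designs have two levels. The 6-level block factor of the
training ANOVA is reported uncorrected as well, matching how such designs
are customarily reported; this is a known limitation, not an oversight.
Unbalanced designs are rejected with a message — consequently the pooled
"active (two groups) vs sham (one group)" training contrast must be run as
balanced pairings (e.g. one active group vs the sham group), and the
training ANOVA's between factor is the training stimulation type.

A property worth knowing when reading residual tables: the decay fit
absorbs part of the polarity square wave (most of what it can absorb is
asymmetric between the early, fast-decaying blocks and the late flat
blocks), which attenuates the subgroup × block-order interaction and can
manufacture a subgroup × period interaction. The headline interaction
survives comfortably at the default effect size, but residual ANOVA
effect sizes are biased toward zero relative to the generating `m`.

## PPV

For k significant outcomes in n independent groups,
`L(p) = C(n,k)·p^k·(1−p)^(n−k)` evaluated at the per-group power (effect
present) and at alpha (no effect);
`PPV = L(power)·prior_odds / (L(power)·prior_odds + L(alpha))`. The
classical computation assumes prior odds 1; the `prior_odds` parameter
(default 1) is an extension for sensitivity analyses. With power 0.8,
alpha 0.05, k = 3, n = 4: L = 0.4096 vs 0.000475, PPV = 0.99884, printed
as 0.998 (three decimals, truncated, i.e. "99.8 %").

## Numerical and scale choices

* All randomness flows from one integer seed through `SeedSequence`
  spawning; equal seeds give byte-identical cohort CSVs.
* Permutation/bootstrap defaults are N = 10,000; the test suite and the
  pipeline's smoke configurations use smaller resampling sizes and cohort
  counts (e.g. 999 resamples × 1,000 null cohorts for calibration, 200
  replicate cohorts for recovery), sizes at which the Monte-Carlo error of
  the checked quantities is far below the tested tolerances.
* Sums of squares below 1e-12 of the response's own scale are treated as
  exact zeros so that fully degenerate designs report F = 0 rather than
  ratios of floating-point dust.
* Ties at the speed maximum take the earliest sample (logged).

## Known limitations

* The generator's square-wave-plus-decay force model and the two-state
  learner are the *assumed* structure of the analyses; the package cannot
  certify behavior under model misspecification it does not simulate.
* The ANOVA engine requires balance (equal subjects per between cell, full
  within grid); general unbalanced mixed models are out of scope — use a
  mixed-effects package for those.
* Real participants' force values are not reproducible here (no deposited
  raw data); published test statistics serve only as directional sanity
  anchors, and none are hard-coded anywhere in the package.
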