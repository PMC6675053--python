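# Methods

## Model

Units are population-rate variables organised into `H` hypercolumns of `U`
units each (uniform `U`; global unit index block `[h·U, (h+1)·U)` belongs to
hypercolumn `h`).  A hard per-hypercolumn winner-take-all stands in for
lateral inhibition: after every integration step exactly one unit per
hypercolumn is active, ties broken toward the lowest index (deterministic;
ties have measure zero under noise).  A pattern (cell assembly) is one
active unit per hypercolumn.

The support current integrates the bias, the recurrent input normalised by
the number of hypercolumns, an intrinsic adaptation current, optional
external cue current and additive white noise; adaptation relaxes toward
the unit's binary activation with the slow time constant.  Integration is
explicit Euler (Euler–Maruyama with noise), default `dt = 0.5 ms`; the step
is guarded by `dt ≤ τ_s/5`.  Defaults: `τ_s = 10 ms`, `τ_a = 250 ms`
(`τ_s < τ_a` is enforced; a ratio above 0.5 warns because the dwell-time
theory assumes separated time scales).

### Noise convention

The user-facing noise parameter is the *output* standard deviation
`σ_out`: away from transitions the current behaves as an
Ornstein–Uhlenbeck process, and the per-step increment
`σ_in·√dt·ξ` with `σ_in = σ_out·√(2/τ_s)` makes the stationary standard
deviation of `s` equal `σ_out` exactly (verified against the closed-form OU
variance in the tests).  Equivalently, the noise enters the current
equation as `τ_s ds = … dt + τ_s σ_in dW`.  All noise levels quoted anywhere
in the API are `σ_out` values, directly comparable in magnitude to weights
and biases.

### Dwell-time theory and tempo control

For orthogonal patterns and homogeneous training, the time an attractor
persists before handing over to its successor is
`T_per = τ_a log(1/(1−B)) + τ_a log(1/(1−τ_s/τ_a))` with
`B = (Δw_next + Δβ_next)/g_a`.  The formula is defined on `0 < B < 1`
(`B ≤ 0`: the successor wins immediately; `B ≥ 1`: adaptation never
overcomes the gap and the pattern persists).  Its exact algebraic inverse,
`B = 1 − e^{−T/τ_a}/(1−τ_s/τ_a)`, `g_a = (Δw+Δβ)/B`, converts a requested
dwell into an adaptation gain; with per-unit gains each pattern's dwell is
set independently.  `gains_for_sequences` assigns each pattern the gain of
its outgoing transition (final patterns inherit their incoming one; units
claimed by several transitions get the mean).  For overlapping patterns the
prediction is approximate and we rely on simulation.

The theory is validated by simulation on a handcrafted chain with equally
spaced weights (`w_self − w_next = w_next − w_rest`): that spacing makes
the two `O(e^{−T/τ_s})` onset transients of the competing currents cancel
to first order, and measured middle dwells agree with the formula within
two integration steps over `B ∈ [0.1, 0.9]`.

### Event extraction and the success criterion

A recall episode is summarised as an ordered list of pattern events.  A
pattern holds a time step when at least `coherence·H` hypercolumn winners
carry its units and strictly more than any other pattern's; maximal runs
longer than `τ_s` become events, shorter runs are discarded as blips (an
activation split by such a blip is re-joined).  The default
`coherence = 0.5` tracks the attractor the network occupies: under noise,
individual hypercolumns flip transiently while the recurrent input
error-corrects them, and demanding instantaneous all-`H` coherence would
miss dwells that are plainly present in the dynamics — it is exactly this
plurality tracking that exposes the error-correcting robustness gained by
adding hypercolumns.  `coherence = 1.0` gives the strict all-units
criterion; for `H = 1` all settings coincide.

A sequence counts as correctly recalled only if, starting from the cued
pattern's first event, the event ids reproduce the entire target order;
skips and transpositions fail, trailing events after completion are
ignored.  Events before the cue pattern first wins are initialization
transients (the biases reflect the end of the training protocol, so the
first WTA settles on the most recently presented pattern until the cue
current takes hold) and are not counted against the recall.

The cue is an additive current to the cue pattern's units (default 50 ms).
Its default amplitude (20) is chosen to dominate the ε-floored weight
range (a trained network inhibits unrelated patterns at pattern-level
weights down to `2·log ε ≈ −32`), so the cue captures the WTA from any
state; the residual decays with `τ_s` and only shifts the cued pattern's
own dwell by a few milliseconds.

## Learning

Every unit carries a pre-synaptic z-trace (slow, default
`τ_z_pre = 25 ms`, validated against the physiologically motivated
5–150 ms range with a warning outside it) and a post-synaptic z-trace
(fast, default `τ_z_post = 5 ms`), both low-pass filters of the binary
activation.  Probability traces accumulate the z-traces; `p_ij` filters
`z_pre,i · z_post,j` (pre on the source/row, post on the target/column —
the pairing that produces forward asymmetry).  Weights/biases are computed
once after training (`w_ij = log(p_ij/(p_i p_j))`, `β_j = log p_j`), with
each probability floored at `ε = 10⁻⁷` only inside the logarithm — traces
themselves start at exactly zero and are never floored.  Recall always
runs with frozen connectivity.

Two probability estimators are provided:

- **ewma** (default): the online p-dynamics integrated offline, an
  exponentially weighted moving average with `τ_p = 5 s`.  Replaying the
  series step by step equals the batch result to float precision.
- **average**: the batch integral formulation, `p = (1/T)∫z dt` — every
  presentation weighs equally.  Used whenever two sequences trained in one
  protocol must compete symmetrically (overlap grids, disambiguation): the
  EWMA penalises the earlier-trained sequence by about `e^{−Δt/τ_p}` in
  every probability (≈ 0.4 in log-odds for a 2 s offset), which is enough
  to decide otherwise-symmetric forks in favour of the later sequence.

Training exploits the piecewise-constant clamp: within a segment of
constant input the discrete Euler recursions are geometric sequences and
sums, so the whole segment is advanced in closed form.  This reproduces
per-step Euler updates to float precision (tested) at a per-segment rather
than per-step cost, making 50-epoch trainings of ~200-unit networks a
matter of milliseconds.

Training input is an activation clamp: the designed `o(t)` drives the
traces directly and never passes through the recurrent dynamics, which
makes offline learning exact and deterministic.  Sequences within one
protocol are presented in order each epoch; when the protocol holds more
than one sequence, every presentation is followed by a silent gap (default
1 s) so traces decouple across sequences, while a single sequence runs its
epochs contiguously (its wrap-around association is a real, intended
feature of the continuous protocol).

## Synthetic data

The generators produce the study conditions themselves: orthogonal pattern
layouts (pattern `k` = local unit `k` everywhere), overlapping sequence
pairs with exact sequential/representational overlap (the overlap window is
centred, never touches sequence endpoints, and uses the same shared
hypercolumn set — the last ones — for every overlapped pair; at
representational overlap 1 window patterns are literally shared ids), and
pulse-train protocols with `T_p = 100 ms`, `IPI = 0`, 50 epochs and 1 s
gaps as the baseline conditions.  They emulate idealized, noiseless,
perfectly timed stimulation; they do not model graded inputs,
per-pattern timing heterogeneity, or stimulus jitter, so passing tests
demonstrate the model's mechanisms under those idealized conditions, not
performance on biological recordings.

## Statistics

Success rates are Bernoulli estimates over independent seeded trials with
Wald 95% intervals (`p̂ ± 1.96·√(p̂(1−p̂)/n)`, clipped to [0, 1]).  Child
seeds are spawned from the master seed by a counter-based scheme so that
increasing the trial count preserves earlier trials.  Noise-free recall is
deterministic, so a single trial decides the estimate.

σ₅₀ — the noise level at which recall success crosses 0.5 — is found by
naive bisection treating the estimates as exact, stopping as soon as 0.5
lies inside the Wald interval at the current midpoint; the result records
the bracket history and final estimate, and an iteration cap raises an
error carrying the partial result.  The machinery is self-tested against a
closed-form injected success curve and an injected Bernoulli ground truth
(interval coverage ≈ 95%).  Default bracket (0, 3) spans the model's noise
range; sweep tests use 200 trials per evaluation (the full-scale runs use
1000), which widens intervals but leaves every reported direction intact.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the whole suite completes in minutes: sequences of length 3–10, 1–10
hypercolumns, 200 Monte-Carlo trials per point, 50–100 training epochs.
These sizes are sufficient because the trained weights reach their
asymptotic shape well before 50 epochs and the directional results are far
larger than the Monte-Carlo error at 200 trials.

## Known limitations

- The dwell-time formula is exact only for orthogonal patterns and
  homogeneous protocols; overlapping-pattern dwells are controlled
  approximately (gains averaged over claiming transitions).
- Sequence disambiguation with fully identical windows: the ε-floor erases
  trained context weights beyond roughly two positions
  (`p ≈ 6·10⁻³·e^{−w·T_p/τ_z_pre}` falls below ε at window 3 for the
  baseline parameters), after which competing branches receive bit-equal
  input and the fork is decided by the WTA tie-break — so at most one of
  the two sequences can be recalled and the zero-noise maximum
  fully-overlapping window measures 2 (1 at long dwells).  Partial overlap
  (context units present) is robust across the whole grid.
- Spiking dynamics, conduction delays, distance-dependent connectivity,
  Dale's-law weight decomposition and online learning during recall are out
  of scope.
- The WTA is hard-wired; no graded activity or multi-winner regimes.
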