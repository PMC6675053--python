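# seqbcpnn

Sequence learning, recall and noise-robustness analysis for a modular
attractor neural network trained with the BCPNN (Bayesian Confidence
Propagation Neural Network) learning rule.

The model is a population-rate network whose units are grouped into
hypercolumns with a hard winner-take-all (WTA): exactly one unit per
hypercolumn is active at any time.  A *pattern* (cell assembly) activates one
unit in every hypercolumn.  Each unit's support current follows

    τ_s ds_j/dt = β_j + (1/H) Σ_i w_ij o_i − g_a a_j − s_j + σ ξ_j + I_j
    o_j = 1 iff s_j is the maximum of its hypercolumn
    τ_a da_j/dt = o_j − a_j

so a cued pattern persists through self-excitation (`w_self`) until its
adaptation current grows enough to hand activity to the successor pattern
through the learned feed-forward weight (`w_next`).  The dwell time of each
attractor obeys the closed form

    T_per = τ_a log(1/(1−B)) + τ_a log(1/(1−τ_s/τ_a)),
    B = (Δw_next + Δβ_next) / g_a,

defined for 0 < B < 1, and inverting it for `g_a` gives direct control of
recall tempo, per pattern if desired.

Weights are not handcrafted but *learned* from a timed stimulation protocol
(pulse time `T_p`, inter-pulse interval `IPI`, epochs).  Two exponential
traces per unit — a slow pre-synaptic z-trace and a fast post-synaptic one —
are accumulated into probability estimates `p_i`, `p_j`, `p_ij`, and the
connectivity is their log-odds:

    w_ij = log(p_ij / (p_i p_j)),   β_j = log(p_j),

with every probability floored at ε = 10⁻⁷ inside the logarithm.  The trace
asymmetry is what writes the *direction* of time into the matrix
(`w_next > w_prev` exactly when the pre trace is slower than the post trace).

The package is aimed at computational neuroscientists studying sequential
memory: it generates pattern sets and protocols (including pairs of
sequences with controlled representational/sequential overlap), trains
connectivity offline, runs cued recall under seeded noise, and provides the
analysis layer (dwell-time theory and inversion, success rates with Wald
intervals, stochastic bisection for the 50% noise threshold σ₅₀, overlap
metrics and disambiguation sweeps).

## Worked example

```python
from dataclasses import replace
from seqbcpnn import *
from seqbcpnn.analysis import gains_for_sequences

patterns = make_orthogonal_patterns(H=1, U=5, n_patterns=5)
sequence = SequenceSpec((0, 1, 2, 3, 4))
series = build_input_series(patterns, [sequence],
                            TrainingProtocol(T_p=100, IPI=0, epochs=50), dt=1.0)
conn, traces = train_offline(series, LearningConfig(tau_z_pre=25, tau_z_post=5))

params = NetworkParams(H=1, N=5, dt=0.5)
t = summarize_transitions(conn, patterns, sequence, params)[2]
print(f"transition {t.from_pattern}->{t.to_pattern}: "
      f"w_self={t.w_self:.2f} w_next={t.w_next:.2f} w_prev={t.w_prev:.2f}")

gains = gains_for_sequences(conn, patterns, [sequence], 100.0, params)
params = replace(params, g_a=gains)
result = run_recall(conn, params, patterns, cue=0, cue_duration=50,
                    total_duration=800, target=sequence)
print("recalled:", result.pattern_ids[:5], "success:", result.success)
print("dwell times (ms):", [float(round(e.duration, 1)) for e in result.events[:5]])

est = estimate_success_rate(conn, params, patterns, sequence,
                            sigma_out=1.0, n_trials=200, seed=0)
print(f"success at sigma=1.0: {est.p_hat:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")
```

prints

```
transition 2->3: w_self=1.38 w_next=-0.00 w_prev=-3.35
recalled: [0, 1, 2, 3, 4] success: True
dwell times (ms): [105.5, 100.0, 100.0, 100.5, 132.5]
success at sigma=1.0: 0.86 (95% CI 0.81-0.91)
```

Reading it: after 50 training epochs the self weight dominates the forward
weight, which dominates the backward one — the learned matrix encodes the
sequence direction.  Setting the adaptation gains for a 100 ms dwell makes
every middle pattern persist 100 ± 0.5 ms (the cued head and the
successor-less tail deviate, as they must), and at a noise level equal to
the typical current difference the sequence is still recalled in full on
86% of trials.

## Command line

Every experiment is also exposed as a subcommand of the `seqbcpnn` console
script, driven by a flat JSON/YAML config plus `--seed`/`--out`/`--fast`
flags:

```bash
seqbcpnn tper-sweep --seed 1 --out results/tper
seqbcpnn sigma50 --config my_config.json --seed 1 --out results/s50 --fast
```

Subcommands: `train`, `recall`, `tper-sweep`, `noise-sweep`, `sigma50`,
`overlap-grid`, `disambiguation`.  Outputs are a config snapshot, tidy
CSV/JSON result tables and a manifest; re-running with the same config and
seed reproduces them bit for bit.

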