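"""BCPNN learning rule with asymmetric synaptic traces.

Two cascaded exponential filters turn the binary activation signal into
probability estimates.  The z-traces low-pass filter the activations —
a slow *pre-synaptic* trace (time constant tau_z_pre) and a fast
*post-synaptic* trace (tau_z_post):

    tau_z_pre  dz_pre_i  = (o_i - z_pre_i)  dt
    tau_z_post dz_post_j = (o_j - z_post_j) dt

and the p-traces accumulate them as exponentially weighted moving averages
of activation and co-activation probabilities:

    tau_p dp_i  = (z_pre_i          - p_i ) dt
    tau_p dp_j  = (z_post_j         - p_j ) dt
    tau_p dp_ij = (z_pre_i z_post_j - p_ij) dt

Weights and biases are the log-odds of the accumulated statistics,

    w_ij = log(p_ij / (p_i p_j)),     beta_j = log(p_j),

with every probability floored at epsilon inside the logarithm.  Because the
pre trace is slower than the post trace, a unit's (lingering) pre trace
overlaps the *next* pattern's post trace during sequential stimulation, which
is exactly what makes w_next exceed w_prev and the learned matrix
asymmetric; with tau_z_pre = tau_z_post the matrix is symmetric.

Every unit carries both a pre- and a post-synaptic trace; w_ij always pairs
pre(i) with post(j).  Traces start at exactly zero; the epsilon floor applies
only inside the logarithm, never in the trace dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Connectivity
from .protocols import InputSeries

__all__ = [
    "LearningConfig",
    "TraceState",
    "update_traces",
    "advance_traces",
    "train_offline",
    "weights_from_probabilities",
    "naive_hebbian_weights",
]


@dataclass(frozen=True)
class LearningConfig:
    """Time constants (ms) of the trace cascade and the probability floor."""

    tau_z_pre: float = 25.0
    tau_z_post: float = 5.0
    tau_p: float = 5000.0
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("tau_z_pre", "tau_z_post", "tau_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if not 5.0 <= self.tau_z_pre <= 150.0:
            warnings.warn(
                "tau_z_pre outside the physiologically motivated 5-150 ms range",
                stacklevel=2,
            )


@dataclass
class TraceState:
    """z- and p-traces for N units (p_joint is N x N, pre index = row)."""

    z_pre: np.ndarray
    z_post: np.ndarray
    p_pre: np.ndarray
    p_post: np.ndarray
    p_joint: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n_units: int) -> "TraceState":
        return cls(
            z_pre=np.zeros(n_units),
            z_post=np.zeros(n_units),
            p_pre=np.zeros(n_units),
            p_post=np.zeros(n_units),
            p_joint=np.zeros((n_units, n_units)),
        )

    def copy(self) -> "TraceState":
        return TraceState(
            z_pre=self.z_pre.copy(), z_post=self.z_post.copy(),
            p_pre=self.p_pre.copy(), p_post=self.p_post.copy(),
            p_joint=self.p_joint.copy(), t=self.t,
        )


def update_traces(
    traces: TraceState, o: np.ndarray, cfg: LearningConfig, dt: float
) -> TraceState:
    """One simultaneous Euler step of the z/p cascade driven by activations o.

    The p-traces consume the z values from *before* this step's z update
    (standard simultaneous Euler on the coupled system).
    """
    if dt > min(cfg.tau_z_pre, cfg.tau_z_post) / 5:
        raise ValueError("dt must be <= min(tau_z_pre, tau_z_post)/5")
    o_f = np.asarray(o, dtype=float)
    z_pre, z_post = traces.z_pre, traces.z_post
    mu = dt / cfg.tau_p
    new = TraceState(
        z_pre=z_pre + (dt / cfg.tau_z_pre) * (o_f - z_pre),
        z_post=z_post + (dt / cfg.tau_z_post) * (o_f - z_post),
        p_pre=traces.p_pre + mu * (z_pre - traces.p_pre),
        p_post=traces.p_post + mu * (z_post - traces.p_post),
        p_joint=traces.p_joint + mu * (np.outer(z_pre, z_post) - traces.p_joint),
        t=traces.t + dt,
    )
    return new


def _geom_sum(r: float, q: float, n: int) -> float:
    # sum_{k=0}^{n-1} q^(n-1-k) r^k
    if abs(r - q) < 1e-12:
        return n * q ** (n - 1)
    return (r ** n - q ** n) / (r - q)


def advance_traces(
    traces: TraceState, o: np.ndarray, n_steps: int, cfg: LearningConfig, dt: float
) -> TraceState:
    """Advance the traces by ``n_steps`` Euler steps of constant input o.

    Evaluates the discrete Euler recursion in closed form (the z-traces are
    geometric sequences and the p-trace updates are geometric sums), so the
    result equals ``n_steps`` calls of :func:`update_traces` to float
    precision at O(N^2) cost per segment instead of per step.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        return traces.copy()
    if dt > min(cfg.tau_z_pre, cfg.tau_z_post) / 5:
        raise ValueError("dt must be <= min(tau_z_pre, tau_z_post)/5")
    o_f = np.asarray(o, dtype=float)
    n = int(n_steps)
    r1 = 1.0 - dt / cfg.tau_z_pre
    r2 = 1.0 - dt / cfg.tau_z_post
    q = 1.0 - dt / cfg.tau_p
    mu = dt / cfg.tau_p

    A = traces.z_pre - o_f          # z_pre_k = o + A r1^k
    B = traces.z_post - o_f         # z_post_k = o + B r2^k
    S1 = _geom_sum(1.0, q, n)       # constant term
    Sr1 = _geom_sum(r1, q, n)
    Sr2 = _geom_sum(r2, q, n)
    Sr12 = _geom_sum(r1 * r2, q, n)

    z_pre = o_f + A * r1 ** n
    z_post = o_f + B * r2 ** n
    p_pre = q ** n * traces.p_pre + mu * (o_f * S1 + A * Sr1)
    p_post = q ** n * traces.p_post + mu * (o_f * S1 + B * Sr2)
    p_joint = (
        q ** n * traces.p_joint
        + mu * (
            np.outer(o_f, o_f) * S1
            + np.outer(o_f, B) * Sr2
            + np.outer(A, o_f) * Sr1
            + np.outer(A, B) * Sr12
        )
    )
    return TraceState(z_pre=z_pre, z_post=z_post, p_pre=p_pre, p_post=p_post,
                      p_joint=p_joint, t=traces.t + n * dt)


def _segment_integrals(traces: TraceState, o: np.ndarray, n: int,
                       cfg: LearningConfig, dt: float):
    """Sums over a constant segment of z_pre, z_post and their outer product
    (z taken at the pre-update state of each step, as the p dynamics do)."""
    o_f = np.asarray(o, dtype=float)
    r1 = 1.0 - dt / cfg.tau_z_pre
    r2 = 1.0 - dt / cfg.tau_z_post
    A = traces.z_pre - o_f
    B = traces.z_post - o_f

    def G(r: float) -> float:
        return (1.0 - r ** n) / (1.0 - r)

    sum_pre = n * o_f + A * G(r1)
    sum_post = n * o_f + B * G(r2)
    sum_joint = (n * np.outer(o_f, o_f) + np.outer(o_f, B) * G(r2)
                 + np.outer(A, o_f) * G(r1) + np.outer(A, B) * G(r1 * r2))
    return sum_pre, sum_post, sum_joint


def train_offline(
    series: InputSeries,
    cfg: LearningConfig,
    record_interval: float | None = None,
    estimator: str = "ewma",
) -> tuple[Connectivity, TraceState]:
    """Integrate the traces over a whole input series and compute the weights.

    Traces start from zero; the connectivity is computed once at the end via
    :func:`weights_from_probabilities` (all experiments separate training
    from recall, so no weights are updated during recall).

    ``estimator`` selects how the probabilities accumulate the z-traces:

    - ``"ewma"``: the exponentially weighted moving average p-dynamics (the
      online rule integrated offline) — recent presentations weigh more,
      with forgetting time tau_p.
    - ``"average"``: the batch integral formulation, p = (1/T) * int z dt —
      every presentation weighs equally.  Use this when comparing or
      competing sequences trained in one protocol, where the EWMA's recency
      bias would break the symmetry between them.

    With ``record_interval`` (ms) set, trace snapshots taken at least that
    far apart (at segment boundaries) are kept on the returned state's
    ``history`` attribute for inspecting the p-trace evolution.
    """
    if series.n_steps == 0:
        raise ValueError("empty input series")
    if estimator not in ("ewma", "average"):
        raise ValueError("estimator must be 'ewma' or 'average'")
    traces = TraceState.zeros(series.n_units)
    history: list[TraceState] = []
    next_record = 0.0
    N = series.n_units
    sums = [np.zeros(N), np.zeros(N), np.zeros((N, N))]
    for o, n in series.segments():
        if estimator == "average":
            for acc, inc in zip(sums, _segment_integrals(traces, o, n, cfg,
                                                         series.dt)):
                acc += inc
        traces = advance_traces(traces, o, n, cfg, series.dt)
        if record_interval is not None and traces.t >= next_record:
            history.append(traces.copy())
            next_record = traces.t + record_interval
    if estimator == "average":
        n_total = series.n_steps
        traces = TraceState(z_pre=traces.z_pre, z_post=traces.z_post,
                            p_pre=sums[0] / n_total, p_post=sums[1] / n_total,
                            p_joint=sums[2] / n_total, t=traces.t)
    conn = weights_from_probabilities(traces, cfg)
    if record_interval is not None:
        traces.history = history  # type: ignore[attr-defined]
    return conn, traces


def weights_from_probabilities(traces: TraceState, cfg: LearningConfig) -> Connectivity:
    """Log-odds weights and log-prior biases with the epsilon floor.

    w_ij = log(max(p_ij, eps) / (max(p_i, eps) * max(p_j, eps))) and
    beta_j = log(max(p_j, eps)); units that were never (co-)active therefore
    get the strong-but-finite inhibition log(eps) instead of -inf.
    """
    eps = cfg.epsilon
    p_i = np.maximum(traces.p_pre, eps)
    p_j = np.maximum(traces.p_post, eps)
    p_ij = np.maximum(traces.p_joint, eps)
    w = np.log(p_ij) - np.log(p_i)[:, None] - np.log(p_j)[None, :]
    beta = np.log(p_j)
    return Connectivity(w=w, beta=beta)


def naive_hebbian_weights(coactivation_counts: np.ndarray) -> np.ndarray:
    """Naive Hebbian baseline: weight = raw co-occurrence frequency.

    Normalised by the total number of observations, so associations observed
    equally often get equal weights regardless of how often each unit was
    active overall — the failure mode the probabilistic rule avoids.
    """
    counts = np.asarray(coactivation_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations")
    return counts / total
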