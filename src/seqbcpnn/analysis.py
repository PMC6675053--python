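"""Persistence-time theory, noise statistics and overlap analysis.

The closed-form theory: during recall of orthogonal patterns the dwell time
of an attractor before it hands over to its successor is

    T_per = tau_a * log(1/(1-B)) + tau_a * log(1/(1 - tau_s/tau_a)),
    B     = (dw_next + dbeta_next) / g_a,

where dw_next = w_self - w_next and dbeta_next = beta_self - beta_next.  B is
defined on (0, 1): B <= 0 means the successor wins immediately (no stable
dwell), B >= 1 means adaptation can never overcome the current difference and
the cued pattern persists forever.  The formula inverts exactly, which is how
a requested dwell time is translated into an adaptation gain.

Noise robustness is summarised by success rates over seeded recall trials
with Wald 95% confidence intervals, and by sigma50 — the noise level at which
the success probability crosses 0.5 — found by stochastic bisection that
stops once 0.5 lies inside the Wald interval of the current estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .learning import LearningConfig, train_offline
from .network import Connectivity, NetworkParams, run_recall
from .protocols import (
    PatternSet,
    SequenceSpec,
    TrainingProtocol,
    build_input_series,
    make_overlapping_pair,
)

__all__ = [
    "PersistenceDomainError",
    "BracketError",
    "Sigma50ConvergenceError",
    "TransitionSummary",
    "SuccessRateEstimate",
    "Sigma50Result",
    "theoretical_persistence_time",
    "persistence_time_from_B",
    "gain_for_target",
    "gain_from_B",
    "summarize_transitions",
    "transitions_frame",
    "gains_for_sequences",
    "estimate_success_rate",
    "find_sigma50",
    "representational_overlap",
    "sequential_overlap",
    "max_disambiguation_window",
]


class PersistenceDomainError(ValueError):
    """Raised when B falls outside (0, 1); carries the offending B."""

    def __init__(self, B: float, message: str | None = None):
        self.B = B
        super().__init__(message or f"persistence time undefined for B={B}")


class BracketError(ValueError):
    """Raised when a sigma50 bracket does not straddle a 0.5 success rate."""


class Sigma50ConvergenceError(RuntimeError):
    """Raised when bisection hits the iteration cap; carries the partial result."""

    def __init__(self, result: "Sigma50Result"):
        self.result = result
        super().__init__(
            f"sigma50 bisection did not satisfy the stopping rule in "
            f"{result.iterations} iterations"
        )


# ---------------------------------------------------------------------------
# Closed-form persistence time and its inverse
# ---------------------------------------------------------------------------

def persistence_time_from_B(B: float, tau_s: float = 10.0, tau_a: float = 250.0) -> float:
    """Dwell time (ms) for a transition parameter B in (0, 1)."""
    if not tau_s < tau_a:
        raise ValueError("tau_s must be smaller than tau_a")
    if not 0.0 < B < 1.0:
        raise PersistenceDomainError(B)
    return tau_a * np.log(1.0 / (1.0 - B)) + tau_a * np.log(1.0 / (1.0 - tau_s / tau_a))


def theoretical_persistence_time(
    dw: float, dbeta: float, g_a: float, tau_s: float = 10.0, tau_a: float = 250.0
) -> float:
    """Predicted dwell time from weight/bias differences and adaptation gain."""
    if g_a <= 0:
        raise ValueError("g_a must be positive")
    return persistence_time_from_B((dw + dbeta) / g_a, tau_s, tau_a)


def gain_from_B(dw: float, dbeta: float, B: float) -> float:
    if not 0.0 < B < 1.0:
        raise PersistenceDomainError(B)
    return (dw + dbeta) / B


def gain_for_target(
    dw: float,
    dbeta: float,
    target_T_per: float,
    tau_s: float = 10.0,
    tau_a: float = 250.0,
) -> float:
    """Exact algebraic inverse of the dwell-time formula.

    Solves T_per(B) = target for B = 1 - exp(-T/tau_a)/(1 - tau_s/tau_a) and
    returns g_a = (dw + dbeta)/B, so that
    ``theoretical_persistence_time(dw, dbeta, gain_for_target(...))`` returns
    the target to machine precision.  Targets at or below the B->0 lower
    bound tau_a*log(1/(1-tau_s/tau_a)) have no valid gain.
    """
    if dw + dbeta <= 0:
        raise ValueError("dw + dbeta must be positive to invert the dwell time")
    if not tau_s < tau_a:
        raise ValueError("tau_s must be smaller than tau_a")
    B = 1.0 - np.exp(-target_T_per / tau_a) / (1.0 - tau_s / tau_a)
    if not 0.0 < B < 1.0:
        raise PersistenceDomainError(
            B, f"target {target_T_per} ms is below the B->0 lower bound"
        )
    return gain_from_B(dw, dbeta, B)


# ---------------------------------------------------------------------------
# Transition summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionSummary:
    """Pattern-level weight structure of one sequence transition k -> k+1.

    Effective (pattern-level) weights average unit-to-unit weights over the
    patterns' unit pairs, matching the 1/H input normalisation of the
    dynamics.  ``w_rest`` is the largest effective outgoing weight after
    w_self, w_next and w_prev.  The predicted dwell time is NaN outside the
    0 < B < 1 domain.
    """

    from_pattern: int
    to_pattern: int
    w_self: float
    w_next: float
    w_prev: float
    w_rest: float
    beta_self: float
    beta_next: float
    dw_next: float
    dbeta_next: float
    B: float
    T_per_predicted: float

    def to_json_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items()}


def _effective_weight(conn: Connectivity, patterns: PatternSet,
                      src: int, dst: int) -> float:
    """Mean unit-level weight from pattern src's units to pattern dst's units."""
    i = patterns.global_units(src)
    j = patterns.global_units(dst)
    return float(conn.w[np.ix_(i, j)].mean())


def summarize_transitions(
    conn: Connectivity,
    patterns: PatternSet,
    seq: SequenceSpec,
    params: NetworkParams,
) -> list[TransitionSummary]:
    """Per-transition weight summary with B and the predicted dwell time.

    ``params.g_a`` may be per-unit; each transition uses the mean gain over
    the active (source) pattern's units.
    """
    ids = seq.pattern_ids
    if max(ids) >= patterns.n_patterns:
        raise ValueError("sequence pattern outside the pattern set")
    g_vec = params.g_a_vector()
    beta_p = {k: float(conn.beta[patterns.global_units(k)].mean()) for k in set(ids)}
    out: list[TransitionSummary] = []
    for k in range(len(ids) - 1):
        P, Q = ids[k], ids[k + 1]
        R = ids[k - 1] if k > 0 else None
        w_self = _effective_weight(conn, patterns, P, P)
        w_next = _effective_weight(conn, patterns, P, Q)
        w_prev = _effective_weight(conn, patterns, P, R) if R is not None else np.nan
        others = [x for x in ids if x not in {P, Q, R}]
        w_rest = max((_effective_weight(conn, patterns, P, x) for x in others),
                     default=np.nan)
        dw = w_self - w_next
        dbeta = beta_p[P] - beta_p[Q]
        g = float(g_vec[patterns.global_units(P)].mean())
        B = (dw + dbeta) / g if g > 0 else np.inf
        try:
            T_pred = persistence_time_from_B(B, params.tau_s, params.tau_a)
        except PersistenceDomainError:
            T_pred = np.nan
        out.append(TransitionSummary(
            from_pattern=P, to_pattern=Q, w_self=w_self, w_next=w_next,
            w_prev=w_prev, w_rest=w_rest, beta_self=beta_p[P],
            beta_next=beta_p[Q], dw_next=dw, dbeta_next=dbeta, B=B,
            T_per_predicted=T_pred,
        ))
    return out


def transitions_frame(summaries: list[TransitionSummary]):
    """Transition summaries as a tidy pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([s.__dict__ for s in summaries])


def gains_for_sequences(
    conn: Connectivity,
    patterns: PatternSet,
    seqs: Sequence[SequenceSpec],
    target_T_per: float,
    params: NetworkParams,
) -> np.ndarray:
    """Per-unit adaptation gains that give every pattern the same dwell time.

    For each transition the inverse dwell-time formula yields the gain for
    the source pattern's units; units claimed by several transitions (e.g.
    patterns shared between two sequences) get the mean of their assigned
    gains, the final pattern of a sequence inherits its incoming transition's
    gain, and unclaimed units fall back to the mean assigned gain.
    """
    N = patterns.n_units
    acc = np.zeros(N)
    cnt = np.zeros(N)
    for seq in seqs:
        summ = summarize_transitions(conn, patterns, seq, params)
        for k, tr in enumerate(summ):
            g = gain_for_target(tr.dw_next, tr.dbeta_next, target_T_per,
                                params.tau_s, params.tau_a)
            units = patterns.global_units(tr.from_pattern)
            acc[units] += g
            cnt[units] += 1
            if k == len(summ) - 1:  # last pattern has no outgoing transition
                units = patterns.global_units(tr.to_pattern)
                acc[units] += g
                cnt[units] += 1
    assigned = cnt > 0
    g_vec = np.full(N, np.nan)
    g_vec[assigned] = acc[assigned] / cnt[assigned]
    g_vec[~assigned] = g_vec[assigned].mean()
    return g_vec


# ---------------------------------------------------------------------------
# Success-rate statistics and sigma50
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuccessRateEstimate:
    """Bernoulli success estimate with a Wald 95% confidence interval."""

    p_hat: float
    n_trials: int
    ci_low: float
    ci_high: float
    seed: int | None = None

    @classmethod
    def from_counts(cls, successes: int, n_trials: int,
                    seed: int | None = None) -> "SuccessRateEstimate":
        p = successes / n_trials
        half = 1.96 * np.sqrt(p * (1.0 - p) / n_trials)
        return cls(p_hat=p, n_trials=n_trials,
                   ci_low=max(0.0, p - half), ci_high=min(1.0, p + half),
                   seed=seed)

    def contains(self, p: float) -> bool:
        return self.ci_low <= p <= self.ci_high


def _default_recall_duration(seq_len: int, T_per_hint: float,
                             cue_duration: float) -> float:
    return cue_duration + 2.5 * (seq_len + 1) * max(T_per_hint, 50.0)


def estimate_success_rate(
    conn: Connectivity | None,
    params: NetworkParams | None,
    patterns: PatternSet | None,
    seq: SequenceSpec | None,
    sigma_out: float,
    n_trials: int,
    seed: int | None = None,
    cue_duration: float = 50.0,
    total_duration: float | None = None,
    cue_amplitude: float = 20.0,
    trial_fn: Callable[[int], bool] | None = None,
) -> SuccessRateEstimate:
    """Fraction of correct recalls over independent seeded trials.

    Child seeds are spawned from ``seed`` with a counter-based scheme, so
    enlarging ``n_trials`` keeps earlier trials identical.  ``trial_fn``
    (child seed -> success) replaces the simulator, e.g. to inject a known
    Bernoulli ground truth when validating the interval machinery.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if trial_fn is None:
        if conn is None or params is None or patterns is None or seq is None:
            raise ValueError("conn/params/patterns/seq required without trial_fn")
        run_params = replace(params, sigma_out=sigma_out)
        if total_duration is None:
            hints = [t.T_per_predicted for t in
                     summarize_transitions(conn, patterns, seq, params)]
            hint = float(np.nanmean(hints)) if np.any(np.isfinite(hints)) else 200.0
            total_duration = _default_recall_duration(len(seq), hint, cue_duration)

        def trial_fn(child_seed: int) -> bool:
            res = run_recall(conn, run_params, patterns, cue=seq.pattern_ids[0],
                             cue_duration=cue_duration,
                             total_duration=total_duration, seed=child_seed,
                             target=seq, cue_amplitude=cue_amplitude)
            return bool(res.success)

        if sigma_out == 0:
            # noise-free recall is deterministic: every trial is identical
            ok = trial_fn(0)
            return SuccessRateEstimate.from_counts(n_trials if ok else 0,
                                                   n_trials, seed=seed)

    children = np.random.SeedSequence(seed).generate_state(n_trials) >> 1
    successes = sum(trial_fn(int(cs)) for cs in children)
    return SuccessRateEstimate.from_counts(successes, n_trials, seed=seed)


@dataclass
class Sigma50Result:
    """Outcome of the stochastic bisection for the 50% noise threshold."""

    sigma50: float
    iterations: int
    final_estimate: SuccessRateEstimate
    bracket_history: list[tuple[float, float]]
    converged: bool = True

    def to_json_dict(self) -> dict:
        return {
            "sigma50": self.sigma50,
            "iterations": self.iterations,
            "converged": self.converged,
            "final_estimate": self.final_estimate.__dict__,
            "bracket_history": self.bracket_history,
        }


def find_sigma50(
    conn: Connectivity | None,
    params: NetworkParams | None,
    patterns: PatternSet | None,
    seq: SequenceSpec | None,
    bracket: tuple[float, float] = (0.0, 3.0),
    n_trials: int = 200,
    seed: int | None = None,
    max_iter: int = 25,
    check_bracket: bool = True,
    rate_fn: Callable[[float, int], SuccessRateEstimate] | None = None,
    **recall_kwargs,
) -> Sigma50Result:
    """Stochastic bisection for the noise level with 50% recall success.

    Bisects on sigma_out using success-rate estimates as if they were exact,
    and stops as soon as 0.5 falls inside the Wald interval of the midpoint
    estimate.  ``rate_fn(sigma, seed) -> SuccessRateEstimate`` substitutes the
    simulator (closed-form oracle injection); otherwise each evaluation runs
    ``n_trials`` seeded recalls.
    """
    lo, hi = bracket
    if not 0 <= lo < hi:
        raise ValueError("bracket must satisfy 0 <= lo < hi")
    ss = np.random.SeedSequence(seed)
    eval_seeds = iter(ss.generate_state(max_iter + 2, dtype=np.uint32).tolist())

    if rate_fn is None:
        def rate_fn(sigma: float, eval_seed: int) -> SuccessRateEstimate:
            return estimate_success_rate(conn, params, patterns, seq, sigma,
                                         n_trials, seed=eval_seed,
                                         **recall_kwargs)

    if check_bracket:
        p_lo = rate_fn(lo, next(eval_seeds))
        p_hi = rate_fn(hi, next(eval_seeds))
        if not (p_lo.p_hat > 0.5 > p_hi.p_hat):
            raise BracketError(
                f"success rate is {p_lo.p_hat:.3f} at sigma={lo} and "
                f"{p_hi.p_hat:.3f} at sigma={hi}: no 0.5 crossing bracketed"
            )

    history: list[tuple[float, float]] = []
    mid_est = None
    mid = 0.5 * (lo + hi)
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        history.append((lo, hi))
        mid_est = rate_fn(mid, next(eval_seeds))
        if mid_est.contains(0.5):
            return Sigma50Result(sigma50=mid, iterations=it,
                                 final_estimate=mid_est,
                                 bracket_history=history)
        if mid_est.p_hat > 0.5:
            lo = mid
        else:
            hi = mid
    partial = Sigma50Result(sigma50=mid, iterations=max_iter,
                            final_estimate=mid_est, bracket_history=history,
                            converged=False)
    raise Sigma50ConvergenceError(partial)


# ---------------------------------------------------------------------------
# Overlap metrics and disambiguation
# ---------------------------------------------------------------------------

def representational_overlap(p1: np.ndarray, p2: np.ndarray) -> float:
    """Fraction of hypercolumns in which two patterns activate the same unit."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("patterns span different numbers of hypercolumns")
    return float(np.mean(p1 == p2))


def sequential_overlap(
    seqA: SequenceSpec, seqB: SequenceSpec, patterns: PatternSet
) -> int:
    """Number of positionally aligned pattern pairs with nonzero overlap."""
    if len(seqA) != len(seqB):
        raise ValueError("sequential overlap is defined for equal-length sequences")
    count = 0
    for a, b in zip(seqA.pattern_ids, seqB.pattern_ids):
        if representational_overlap(patterns.patterns[a], patterns.patterns[b]) > 0:
            count += 1
    return count


def max_disambiguation_window(
    length: int,
    H: int,
    U: int,
    protocol: TrainingProtocol,
    learning_cfg: LearningConfig,
    params: NetworkParams,
    target_T_per: float = 50.0,
    sigma_out: float = 0.0,
    seed: int | None = None,
    n_trials: int = 200,
    cue_duration: float = 50.0,
    training_dt: float = 1.0,
) -> tuple[int, list[dict]]:
    """Largest fully-overlapping window both sequences survive.

    For each window size w the two length-``length`` sequences whose middle w
    patterns are *identical* (representational overlap 1) are trained from
    scratch, per-unit gains are set for ``target_T_per``, and both sequences
    are cued.  At zero noise "solved" means both recalls are exactly correct;
    under noise it means both estimated success rates exceed 0.5.  Returns the
    largest solved w (0 if none) and a per-window report.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    best = 0
    report: list[dict] = []
    ss = np.random.SeedSequence(seed)
    for w in range(1, length - 1):
        pset, seqA, seqB = make_overlapping_pair(H, U, length, w, 1.0)
        series = build_input_series(pset, [seqA, seqB], protocol, dt=training_dt)
        # batch time-average estimator: the EWMA's recency bias would favour
        # whichever sequence was presented last at the symmetric fork
        conn, _ = train_offline(series, learning_cfg, estimator="average")
        run_params = replace(params, H=H, N=pset.n_units, g_a=1.0)
        g_vec = gains_for_sequences(conn, pset, [seqA, seqB], target_T_per,
                                    run_params)
        run_params = replace(run_params, g_a=g_vec)
        total = _default_recall_duration(length, target_T_per, cue_duration)
        entry = {"window": w}
        if sigma_out == 0:
            ok = True
            for name, seq in (("A", seqA), ("B", seqB)):
                res = run_recall(conn, run_params, pset, cue=seq.pattern_ids[0],
                                 cue_duration=cue_duration, total_duration=total,
                                 target=seq)
                entry[f"success_{name}"] = bool(res.success)
                ok = ok and bool(res.success)
        else:
            child = ss.spawn(1)[0].generate_state(2, dtype=np.uint32).tolist()
            ok = True
            for name, seq, s in (("A", seqA, child[0]), ("B", seqB, child[1])):
                est = estimate_success_rate(conn, run_params, pset, seq,
                                            sigma_out, n_trials, seed=s,
                                            cue_duration=cue_duration,
                                            total_duration=total)
                entry[f"p_hat_{name}"] = est.p_hat
                ok = ok and est.p_hat > 0.5
        entry["solved"] = ok
        report.append(entry)
        if ok:
            best = w
    return best, report
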