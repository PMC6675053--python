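"""Rate dynamics of the modular attractor network.

Each unit carries a support current ``s`` driven by its bias, by the
recurrent input (1/H) * sum_i w_ij o_i, by an intrinsic adaptation current
``-g_a * a`` and by an optional external cue current; a hard per-hypercolumn
winner-take-all (WTA) turns the currents into a binary activation vector
``o`` with exactly one winner per hypercolumn:

    tau_s ds_j = (beta_j + (1/H) sum_i w_ij o_i - g_a a_j - s_j + I_j) dt
                 + tau_s sigma_in dW_j
    o_j = 1  iff  s_j is the maximum of its hypercolumn
    tau_a da_j = (o_j - a_j) dt

Integration is explicit Euler (Euler-Maruyama for the noise term).  Noise is
parameterised by the *output* standard deviation sigma_out: away from
transitions ``s`` behaves as an Ornstein-Uhlenbeck process, and the per-step
increment sigma_in*sqrt(dt)*xi with sigma_in = sigma_out*sqrt(2/tau_s) gives
a stationary standard deviation of exactly sigma_out.  This convention is the
package's contract for all noise levels quoted anywhere in the API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .protocols import PatternSet, SequenceSpec, make_orthogonal_patterns

__all__ = [
    "NetworkParams",
    "NetworkState",
    "Connectivity",
    "PatternEvent",
    "RecallResult",
    "IntegrationError",
    "wta_select",
    "step_dynamics",
    "run_recall",
    "detect_pattern_activations",
    "evaluate_success",
    "sequence_chain_connectivity",
]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class NetworkParams:
    """Dynamical parameters of the rate network.

    ``g_a`` may be a scalar or a per-unit vector (per-unit gains are how the
    temporal structure of a recalled sequence is controlled).  ``sigma_out``
    is the target stationary standard deviation of the support current under
    noise, in the same (dimensionless) current units as the weights.
    """

    H: int
    N: int
    tau_s: float = 10.0
    tau_a: float = 250.0
    g_a: float | np.ndarray = 1.0
    sigma_out: float = 0.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.N % self.H != 0:
            raise ValueError("N must be a multiple of H (uniform hypercolumns)")
        if self.N // self.H < 1:
            raise ValueError("every hypercolumn needs at least one unit")
        if not self.tau_s < self.tau_a:
            raise ValueError("tau_s must be smaller than tau_a")
        if self.tau_s / self.tau_a > 0.5:
            warnings.warn(
                "tau_s/tau_a > 0.5: the separation of time scales behind the "
                "persistence-time theory is weak", stacklevel=2,
            )
        if self.sigma_out < 0:
            raise ValueError("sigma_out must be >= 0")
        g = np.asarray(self.g_a, dtype=float)
        if np.any(g < 0):
            raise ValueError("g_a must be >= 0 elementwise")
        if g.ndim not in (0, 1) or (g.ndim == 1 and g.shape[0] != self.N):
            raise ValueError("g_a must be a scalar or a length-N vector")
        if self.dt > self.tau_s / 5:
            raise ValueError("dt must be <= tau_s/5 for a stable Euler step")

    @property
    def U(self) -> int:
        return self.N // self.H

    @property
    def sigma_in(self) -> float:
        """Input noise amplitude giving stationary Std[s] = sigma_out."""
        return self.sigma_out * np.sqrt(2.0 / self.tau_s)

    def g_a_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.g_a, dtype=float), (self.N,)).copy()


@dataclass
class NetworkState:
    """Support currents, activations and adaptation at one time point."""

    s: np.ndarray
    o: np.ndarray
    a: np.ndarray
    t: float = 0.0


@dataclass
class Connectivity:
    """Learned weight matrix and bias vector.

    ``w[i, j]`` is the weight from (pre-synaptic) unit ``i`` to unit ``j``;
    ``beta`` the per-unit bias (log prior activation probability).
    """

    w: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("w must be a square matrix")
        if self.beta.shape != (self.w.shape[0],):
            raise ValueError("beta length must match w")

    @property
    def N(self) -> int:
        return self.w.shape[0]

    def validate(self, epsilon: float = 1e-7) -> None:
        """Check finiteness and the bounds implied by the epsilon-floor.

        With probabilities floored at ``epsilon`` before the logarithm and
        p_ij <= min(p_i, p_j) (which the trace dynamics guarantee from zero
        initial conditions), every weight lies in [2 log eps, -log eps] and
        every bias in [log eps, 0].
        """
        if not (np.all(np.isfinite(self.w)) and np.all(np.isfinite(self.beta))):
            raise ValueError("non-finite connectivity entries")
        lo, hi = 2 * np.log(epsilon), -np.log(epsilon)
        if self.w.min() < lo - 1e-9 or self.w.max() > hi + 1e-9:
            raise ValueError("weights outside the epsilon-floor bounds")
        if self.beta.min() < np.log(epsilon) - 1e-9 or self.beta.max() > 1e-9:
            raise ValueError("biases outside the epsilon-floor bounds")

    def save(self, path: str, **metadata) -> None:
        import json
        from pathlib import Path

        np.savez_compressed(path, w=self.w, beta=self.beta)
        Path(str(path) + ".json").write_text(json.dumps(metadata, indent=2, default=str))


@dataclass(frozen=True)
class PatternEvent:
    pattern_id: int
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class RecallResult:
    """Ordered pattern activation events of one recall episode."""

    events: list[PatternEvent]
    success: bool | None = None
    trajectories: dict | None = None

    @property
    def persistence_times(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    @property
    def pattern_ids(self) -> list[int]:
        return [e.pattern_id for e in self.events]

    def to_json_dict(self) -> dict:
        return {
            "events": [
                {"pattern_id": e.pattern_id, "onset": e.onset, "offset": e.offset}
                for e in self.events
            ],
            "persistence_times": self.persistence_times.tolist(),
            "success": self.success,
        }


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def wta_select(s: np.ndarray, H: int) -> np.ndarray:
    """Hard winner-take-all: one active unit (the argmax of s) per hypercolumn.

    Ties break toward the lowest unit index (deterministic; ties have measure
    zero under noise).
    """
    s = np.asarray(s, dtype=float)
    N = s.shape[0]
    if H < 1 or N % H != 0 or N // H < 1:
        raise ValueError("layout does not partition the units into hypercolumns")
    U = N // H
    winners = s.reshape(H, U).argmax(axis=1)
    o = np.zeros(N, dtype=bool)
    o[np.arange(H) * U + winners] = True
    return o


def _drift(s, o, a, conn, params, I):
    rec = (conn.w.T @ o) / params.H
    return conn.beta + rec - np.asarray(params.g_a) * a - s + I


def step_dynamics(
    state: NetworkState,
    conn: Connectivity,
    params: NetworkParams,
    I: np.ndarray | float = 0.0,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """One Euler(-Maruyama) step of the coupled s/a dynamics followed by WTA."""
    dt = params.dt
    o_f = state.o.astype(float)
    ds = (dt / params.tau_s) * _drift(state.s, o_f, state.a, conn, params, I)
    if params.sigma_out > 0:
        if rng is None:
            raise ValueError("rng is required when sigma_out > 0")
        ds = ds + params.sigma_in * np.sqrt(dt) * rng.standard_normal(params.N)
    s_new = state.s + ds
    a_new = state.a + (dt / params.tau_a) * (o_f - state.a)
    if not np.all(np.isfinite(s_new)):
        raise IntegrationError(f"non-finite support current at t={state.t}")
    return NetworkState(s=s_new, o=wta_select(s_new, params.H), a=a_new,
                        t=state.t + dt)


def initial_state(conn: Connectivity, params: NetworkParams) -> NetworkState:
    """Noise-free input-free asymptote: s = beta, a = 0, o from the first WTA."""
    s = conn.beta.astype(float).copy()
    return NetworkState(s=s, o=wta_select(s, params.H), a=np.zeros(params.N))


def _recall_loop_py(wT, beta, g_a, I_cue, n_cue, noise, dt, tau_s, tau_a,
                    H, U, n_steps, s_t=None, a_t=None):
    """Reference integration loop (same arithmetic as the jitted kernel)."""
    N = H * U
    s = beta.copy()
    a = np.zeros(N)
    hc_offset = np.arange(H) * U
    winners = s.reshape(H, U).argmax(axis=1)
    active = hc_offset + winners
    o = np.zeros(N)
    o[active] = 1.0
    winners_t = np.empty((n_steps, H), dtype=np.int32)
    cs, ca = dt / tau_s, dt / tau_a
    for k in range(n_steps):
        rec = wT[:, active].sum(axis=1) / H
        drift = beta + rec - g_a * a - s
        if k < n_cue:
            drift = drift + I_cue
        s = s + cs * drift
        if noise is not None:
            s = s + noise[k]
        a = a + ca * (o - a)
        winners = s.reshape(H, U).argmax(axis=1)
        active = hc_offset + winners
        o[:] = 0.0
        o[active] = 1.0
        winners_t[k] = winners
        if s_t is not None:
            s_t[k] = s
            a_t[k] = a
    return winners_t, s, a


try:  # jitted hot loop; the pure-numpy reference above defines the semantics
    import numba as _nb

    @_nb.njit(cache=True)
    def _recall_loop_jit(wT, beta, g_a, I_cue, n_cue, noise, use_noise,
                         dt, tau_s, tau_a, H, U, n_steps):  # pragma: no cover
        N = H * U
        s = beta.copy()
        a = np.zeros(N)
        o = np.zeros(N)
        winners = np.empty(H, dtype=np.int64)
        for h in range(H):
            best = h * U
            for u in range(1, U):
                if s[h * U + u] > s[best]:
                    best = h * U + u
            winners[h] = best - h * U
            o[best] = 1.0
        winners_t = np.empty((n_steps, H), dtype=np.int32)
        cs = dt / tau_s
        ca = dt / tau_a
        rec = np.empty(N)
        for k in range(n_steps):
            for j in range(N):
                acc = 0.0
                for h in range(H):
                    acc += wT[j, h * U + winners[h]]
                rec[j] = acc / H
            for j in range(N):
                drift = beta[j] + rec[j] - g_a[j] * a[j] - s[j]
                if k < n_cue:
                    drift += I_cue[j]
                s[j] = s[j] + cs * drift
                if use_noise:
                    s[j] += noise[k, j]
                a[j] = a[j] + ca * (o[j] - a[j])
            for h in range(H):
                best = h * U
                for u in range(1, U):
                    if s[h * U + u] > s[best]:
                        best = h * U + u
                winners[h] = best - h * U
            for j in range(N):
                o[j] = 0.0
            for h in range(H):
                o[h * U + winners[h]] = 1.0
            for h in range(H):
                winners_t[k, h] = winners[h]
        return winners_t, s, a

except Exception:  # pragma: no cover
    _recall_loop_jit = None


def run_recall(
    conn: Connectivity,
    params: NetworkParams,
    patterns: PatternSet,
    cue: int,
    cue_duration: float = 50.0,
    total_duration: float = 1000.0,
    seed: int | None = None,
    target: SequenceSpec | None = None,
    cue_amplitude: float = 20.0,
    record_trajectories: bool = False,
    coherence: float = 0.5,
) -> RecallResult:
    """Cue a pattern with a strong external current and let recall unfold.

    The cue current ``cue_amplitude`` is applied to the cue pattern's units
    for ``cue_duration`` ms, after which the network runs free for the rest of
    ``total_duration``.  The default amplitude is chosen to dominate the
    epsilon-floored weight range of trained connectivity (|w| can reach
    -log(1e-7) ~ 16 against a strongly inhibited pattern), so a cue reliably
    captures the winner-take-all even from an unrelated attractor state; its
    residual decays with tau_s and only shifts the cued pattern's own dwell.  Pattern activation events are extracted afterwards
    (a pattern counts as active only while *all* of its H units win their
    hypercolumns for longer than tau_s) and, if ``target`` is given, success
    is the conservative full-order criterion of :func:`evaluate_success`.
    """
    if total_duration < cue_duration:
        raise ValueError("total_duration must be >= cue_duration")
    if not 0 <= cue < patterns.n_patterns:
        raise ValueError("cue pattern does not exist")
    dt = params.dt
    n_steps = int(round(total_duration / dt))
    n_cue = int(round(cue_duration / dt))
    H, N, U = params.H, params.N, params.U
    g_a = params.g_a_vector()
    noisy = params.sigma_out > 0
    if noisy:
        rng = np.random.default_rng(seed)
        noise = params.sigma_in * np.sqrt(dt) * rng.standard_normal((n_steps, N))
    else:
        noise = None

    I_cue = np.zeros(N)
    I_cue[patterns.global_units(cue)] = cue_amplitude
    beta = conn.beta.astype(float)
    wT = np.ascontiguousarray(conn.w.T)

    if _recall_loop_jit is not None and not record_trajectories:
        dummy = np.zeros((1, 1)) if noise is None else noise
        winners_t, s, a = _recall_loop_jit(
            wT, beta, g_a, I_cue, n_cue, dummy, noise is not None,
            float(dt), params.tau_s, params.tau_a, H, U, n_steps)
    else:
        s_t = np.empty((n_steps, N)) if record_trajectories else None
        a_t = np.empty((n_steps, N)) if record_trajectories else None
        winners_t, s, a = _recall_loop_py(
            wT, beta, g_a, I_cue, n_cue, noise, dt, params.tau_s,
            params.tau_a, H, U, n_steps, s_t=s_t, a_t=a_t)
    if not np.all(np.isfinite(s)):
        raise IntegrationError("non-finite support current during recall")

    events = _events_from_winners(winners_t, patterns, params,
                                  coherence=coherence)
    success = evaluate_success(events, target) if target is not None else None
    traj = None
    if record_trajectories:
        o_t = np.zeros((n_steps, N), dtype=bool)
        offs = np.arange(H) * U
        for k in range(n_steps):
            o_t[k, offs + winners_t[k]] = True
        traj = {"s": s_t, "a": a_t, "o": o_t, "t": (np.arange(n_steps) + 1) * dt}
    return RecallResult(events=events, success=success, trajectories=traj)


# ---------------------------------------------------------------------------
# Event extraction and the success criterion
# ---------------------------------------------------------------------------

def _winner_rows(o_timeseries: np.ndarray, H: int) -> np.ndarray:
    T, N = o_timeseries.shape
    U = N // H
    return o_timeseries.reshape(T, H, U).argmax(axis=2).astype(np.int32)


def _events_from_winners(
    winners_t: np.ndarray,
    patterns: PatternSet,
    params: NetworkParams,
    coherence: float = 0.5,
) -> list[PatternEvent]:
    dt = params.dt
    T, H = winners_t.shape
    if T == 0:
        return []
    P = patterns.n_patterns
    # per step, how many hypercolumn winners carry each pattern's unit
    counts = np.zeros((T, P), dtype=np.int32)
    for p in range(P):
        counts[:, p] = (winners_t == patterns.patterns[p][None, :]).sum(axis=1)
    best = counts.argmax(axis=1)
    c1 = counts[np.arange(T), best]
    if P > 1:
        order = np.argsort(counts, axis=1)
        c2 = counts[np.arange(T), order[:, -2]]
    else:
        c2 = np.full(T, -1, dtype=np.int32)
    need = max(coherence * H, 1.0)
    labels = np.where((c1 >= need) & (c1 > c2), best, -1).astype(np.int64)

    # maximal constant runs of the dominant label
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [T]))
    events: list[PatternEvent] = []
    min_steps = params.tau_s / dt  # strictly longer than tau_s
    for a, b in zip(bounds[:-1], bounds[1:]):
        pid = int(labels[a])
        if pid < 0 or (b - a) <= min_steps:
            continue
        onset, offset = a * dt, b * dt
        if events and events[-1].pattern_id == pid:
            # a sub-tau_s blip split one activation in two; re-join it
            events[-1] = PatternEvent(pid, events[-1].onset, offset)
        else:
            events.append(PatternEvent(pid, onset, offset))
    return events


def detect_pattern_activations(
    o_timeseries: np.ndarray,
    patterns: PatternSet,
    params: NetworkParams,
    coherence: float = 0.5,
) -> list[PatternEvent]:
    """Maximal intervals during which one pattern dominates the activity.

    A pattern holds a time step when at least ``coherence * H`` hypercolumns
    (and strictly more than for any other pattern) activate its units; with
    ``coherence=1.0`` this is the strict all-units-co-active rule, and for a
    single hypercolumn the two coincide.  The plurality default makes event
    extraction robust to sub-threshold hypercolumn flips under noise, which
    is what gives modular networks their error-correcting robustness.
    Intervals not exceeding tau_s are discarded as blips (and an activation
    interrupted by such a blip is re-joined).
    """
    o = np.asarray(o_timeseries, dtype=bool)
    return _events_from_winners(_winner_rows(o, params.H), patterns, params,
                                coherence=coherence)


def evaluate_success(events: list[PatternEvent], target: SequenceSpec) -> bool:
    """Conservative criterion: starting from the cued pattern's first event,
    the recalled ids must reproduce the full target order; any skip or
    out-of-order activation fails.  Events before the cue pattern first wins
    (initial WTA settling while the cue current builds up) and extra trailing
    events after the target completes are ignored."""
    ids = [e.pattern_id for e in events]
    want = list(target.pattern_ids)
    try:
        start = ids.index(want[0])
    except ValueError:
        return False
    ids = ids[start:]
    if len(ids) < len(want):
        return False
    return ids[: len(want)] == want


# ---------------------------------------------------------------------------
# Handcrafted connectivity
# ---------------------------------------------------------------------------

def sequence_chain_connectivity(
    n_patterns: int,
    H: int = 1,
    w_self: float = 2.0,
    w_next: float = 1.0,
    w_rest: float = 0.0,
    beta: float | np.ndarray = 0.0,
    U: int | None = None,
) -> tuple[Connectivity, PatternSet]:
    """Idealised chain connectivity over orthogonal patterns.

    Diagonal blocks carry ``w_self`` (pattern self-excitation), the first
    super-diagonal ``w_next`` (feed-forward drive to the successor) and every
    other pair ``w_rest`` (background inhibition); the chain is the classic
    handcrafted wiring that produces cued sequential recall.
    """
    if not (w_self > w_next > w_rest):
        raise ValueError("need w_self > w_next > w_rest for an ordered chain")
    U = n_patterns if U is None else U
    pats = make_orthogonal_patterns(H, U, n_patterns)
    N = H * U
    w = np.full((N, N), w_rest, dtype=float)
    for k in range(n_patterns):
        src = pats.global_units(k)
        w[np.ix_(src, src)] = w_self
        if k + 1 < n_patterns:
            w[np.ix_(src, pats.global_units(k + 1))] = w_next
    beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (N,)).copy()
    return Connectivity(w=w, beta=beta_vec), pats
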