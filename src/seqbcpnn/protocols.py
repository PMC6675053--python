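"""Pattern sets, sequence specifications and timed training input.

The network stores *patterns*: cell assemblies that activate exactly one unit
in each of ``H`` hypercolumns.  Training is driven purely by a designed
activation time series (an activation clamp): a sequence is presented as a
train of pulses of duration ``T_p`` separated by silent inter-pulse intervals
(IPI), repeated for a number of epochs.  The clamp feeds the learning traces
directly; it does not pass through the recurrent dynamics, which makes batch
learning exact and deterministic.

Unit indexing convention: hypercolumn ``h`` owns the contiguous global index
block ``[h*U, (h+1)*U)``; a pattern is stored as its per-hypercolumn local
unit indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatternSet",
    "SequenceSpec",
    "TrainingProtocol",
    "InputSeries",
    "CapacityError",
    "PlacementError",
    "make_orthogonal_patterns",
    "make_overlapping_pair",
    "build_input_series",
    "build_pair_association_series",
]


class CapacityError(ValueError):
    """Raised when a pattern layout needs more units per hypercolumn than exist."""


class PlacementError(ValueError):
    """Raised when an overlap window cannot be placed inside a sequence."""


@dataclass(frozen=True)
class PatternSet:
    """An ordered collection of minicolumn-coded patterns.

    Parameters
    ----------
    H : int
        Number of hypercolumns.
    units_per_hypercolumn : int
        Units ``U`` in every hypercolumn (uniform).
    patterns : np.ndarray
        Integer array of shape ``(n_patterns, H)``; entry ``[k, h]`` is the
        local index (in ``[0, U)``) of the unit pattern ``k`` activates in
        hypercolumn ``h``.
    """

    H: int
    units_per_hypercolumn: int
    patterns: np.ndarray

    def __post_init__(self) -> None:
        pats = np.asarray(self.patterns, dtype=np.int64)
        if pats.ndim != 2 or pats.shape[1] != self.H:
            raise ValueError(f"patterns must have shape (n, H={self.H})")
        if pats.size and (pats.min() < 0 or pats.max() >= self.units_per_hypercolumn):
            raise ValueError("pattern unit index outside [0, U)")
        object.__setattr__(self, "patterns", pats)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        """Total unit count N = H * U."""
        return self.H * self.units_per_hypercolumn

    def global_units(self, pattern_id: int) -> np.ndarray:
        """Global unit indices (one per hypercolumn) of a pattern."""
        offsets = np.arange(self.H) * self.units_per_hypercolumn
        return offsets + self.patterns[pattern_id]

    def unit_mask(self, pattern_id: int) -> np.ndarray:
        """Boolean activation vector of length N for a pattern."""
        mask = np.zeros(self.n_units, dtype=bool)
        mask[self.global_units(pattern_id)] = True
        return mask


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered list of pattern ids to be learned/recalled as a sequence."""

    pattern_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.pattern_ids)
        if len(ids) < 2:
            raise ValueError("a sequence needs at least 2 patterns")
        for a, b in zip(ids, ids[1:]):
            if a == b:
                raise ValueError("immediate repetition of a pattern is not allowed")
        object.__setattr__(self, "pattern_ids", ids)

    def __len__(self) -> int:
        return len(self.pattern_ids)


@dataclass(frozen=True)
class TrainingProtocol:
    """Timing of the pulse-train presentation used for training.

    ``T_p`` is the pulse (clamp) duration per pattern, ``IPI`` the silent
    interval between pulses, both in ms.  Distinct sequences in one protocol
    are separated by ``inter_sequence_gap`` (1 s by default) so that their
    traces decouple.
    """

    T_p: float = 100.0
    IPI: float = 0.0
    epochs: int = 1
    inter_sequence_gap: float = 1000.0
    clamp_mode: str = "activation"

    def __post_init__(self) -> None:
        if self.T_p <= 0:
            raise ValueError("T_p must be positive")
        if self.IPI < 0 or self.inter_sequence_gap < 0:
            raise ValueError("IPI and inter_sequence_gap must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class InputSeries:
    """A discretised activation clamp: time steps x units boolean matrix."""

    dt: float
    o_clamped: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        o = np.asarray(self.o_clamped, dtype=bool)
        object.__setattr__(self, "o_clamped", o)

    @property
    def n_steps(self) -> int:
        return self.o_clamped.shape[0]

    @property
    def n_units(self) -> int:
        return self.o_clamped.shape[1]

    def segments(self) -> list[tuple[np.ndarray, int]]:
        """Runs of constant activation as ``(o_vector, n_steps)`` pairs.

        The clamp is piecewise constant by construction, so learning can be
        advanced segment-by-segment in closed form.
        """
        o = self.o_clamped
        if o.shape[0] == 0:
            return []
        change = np.flatnonzero(np.any(o[1:] != o[:-1], axis=1)) + 1
        bounds = np.concatenate(([0], change, [o.shape[0]]))
        return [(o[a], int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]

    def save(self, path: str) -> None:
        """Export to a compressed array file with a JSON metadata sidecar."""
        import json
        from pathlib import Path

        np.savez_compressed(path, o_clamped=self.o_clamped)
        meta = {"dt": self.dt, "total_duration": self.total_duration,
                "n_steps": self.n_steps, "n_units": self.n_units}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Pattern generators
# ---------------------------------------------------------------------------

def make_orthogonal_patterns(H: int, U: int, n_patterns: int) -> PatternSet:
    """Canonical non-overlapping layout: pattern ``k`` activates local unit
    ``k`` in every hypercolumn.

    Raises
    ------
    CapacityError
        If ``n_patterns > U`` (pigeonhole: patterns could not stay disjoint).
    """
    if n_patterns > U:
        raise CapacityError(
            f"cannot place {n_patterns} disjoint patterns with U={U} units per hypercolumn"
        )
    pats = np.tile(np.arange(n_patterns)[:, None], (1, H))
    return PatternSet(H=H, units_per_hypercolumn=U, patterns=pats)


def make_overlapping_pair(
    H: int,
    U: int,
    length: int,
    sequential_overlap: int,
    representational_overlap: float,
    seed: int | None = None,
    random_placement: bool = False,
) -> tuple[PatternSet, SequenceSpec, SequenceSpec]:
    """Build two equal-length sequences with a controlled overlap window.

    ``sequential_overlap`` positionally aligned pattern pairs in the middle of
    the two sequences share the active unit in
    ``representational_overlap * H`` hypercolumns (the same hypercolumn set —
    the last ones — for every overlapped pair).  With representational
    overlap 1 the window patterns are *identical* (shared pattern ids): the
    sequence-disambiguation regime.  All other patterns are pairwise disjoint.

    The window never includes the first or last pattern of either sequence.
    By default it is centred; with ``random_placement`` its start is drawn
    uniformly among valid placements using ``seed``.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    w = int(sequential_overlap)
    if w < 0:
        raise ValueError("sequential_overlap must be >= 0")
    if not 0.0 <= representational_overlap <= 1.0:
        raise ValueError("representational_overlap must be in [0, 1]")
    n_shared = representational_overlap * H
    if abs(n_shared - round(n_shared)) > 1e-9:
        raise ValueError(
            f"representational_overlap*H = {n_shared} does not round to a whole "
            "number of shared hypercolumns"
        )
    n_shared = int(round(n_shared))
    if n_shared == 0 or w == 0:
        # No actual overlap anywhere; keep the two sequences fully disjoint.
        w, n_shared = 0, 0
    if w > length - 2:
        raise PlacementError(
            f"a window of {w} patterns cannot avoid the endpoints of a "
            f"length-{length} sequence"
        )
    if w:
        if random_placement:
            rng = np.random.default_rng(seed)
            start = int(rng.integers(1, length - w))
        else:
            start = (length - w + 1) // 2
            start = min(max(start, 1), length - 1 - w)
    else:
        start = 0

    identical = w > 0 and n_shared == H

    # Column budget per hypercolumn: A uses one fresh column per pattern; B's
    # non-window patterns and (partially overlapped) window patterns each need
    # their own fresh column in the non-shared hypercolumns.
    n_b_own = (length - w) + (w if (w and not identical) else 0)
    if length + n_b_own > U:
        raise CapacityError(
            f"need {length + n_b_own} unit columns per hypercolumn but U={U}"
        )

    patterns: list[np.ndarray] = []
    a_ids: list[int] = []
    b_ids: list[int] = []

    def add(row: np.ndarray) -> int:
        patterns.append(row)
        return len(patterns) - 1

    next_col = 0
    for k in range(length):
        a_ids.append(add(np.full(H, next_col)))
        next_col += 1
    for k in range(length):
        in_window = w > 0 and start <= k < start + w
        if in_window and identical:
            b_ids.append(a_ids[k])
            continue
        row = np.full(H, next_col)
        next_col += 1
        if in_window:
            # share the active unit of A's pattern in the LAST n_shared
            # hypercolumns (fixed set for every overlapped pair)
            row = row.copy()
            row[H - n_shared:] = patterns[a_ids[k]][H - n_shared:]
        b_ids.append(add(row))

    pset = PatternSet(H=H, units_per_hypercolumn=U, patterns=np.array(patterns))
    return pset, SequenceSpec(tuple(a_ids)), SequenceSpec(tuple(b_ids))


# ---------------------------------------------------------------------------
# Input series construction
# ---------------------------------------------------------------------------

def build_input_series(
    patterns: PatternSet,
    sequences: list[SequenceSpec],
    protocol: TrainingProtocol,
    dt: float,
) -> InputSeries:
    """Lay out the pulse-train clamp o(t) for a training protocol.

    Pulses appear in sequence order, repeated for ``protocol.epochs``.  When
    the protocol contains more than one sequence, an ``inter_sequence_gap`` of
    silence follows every sequence presentation (so traces decouple across
    sequences); a single sequence is presented with contiguous epochs.
    """
    if not sequences:
        raise ValueError("at least one sequence is required")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_p = max(1, round(protocol.T_p / dt))
    n_ipi = round(protocol.IPI / dt)
    n_gap = round(protocol.inter_sequence_gap / dt)
    use_gap = len(sequences) > 1

    masks = {k: patterns.unit_mask(k) for k in range(patterns.n_patterns)}
    blocks: list[np.ndarray] = []
    N = patterns.n_units
    zero_row = np.zeros((1, N), dtype=bool)
    for _ in range(protocol.epochs):
        for si, seq in enumerate(sequences):
            for pid in seq.pattern_ids:
                blocks.append(np.repeat(masks[pid][None, :], n_p, axis=0))
                if n_ipi:
                    blocks.append(np.repeat(zero_row, n_ipi, axis=0))
            if use_gap and n_gap:
                blocks.append(np.repeat(zero_row, n_gap, axis=0))
    # no trailing gap after the final presentation
    if use_gap and n_gap:
        blocks.pop()
    o = np.concatenate(blocks, axis=0)
    return InputSeries(dt=dt, o_clamped=o, total_duration=o.shape[0] * dt)


def build_pair_association_series(
    associations: list[tuple[int, int, int]],
    n_units: int,
    T_p: float = 100.0,
    gap: float = 500.0,
    dt: float = 1.0,
    seed: int | None = None,
) -> InputSeries:
    """Encode counted pairwise temporal associations as a pulse series.

    Each association ``(pre, post, count)`` contributes ``count``
    presentations of the two-pulse motif *pre then post*; presentations are
    shuffled (seeded) and separated by silent gaps much longer than the
    synaptic traces so motifs do not associate with each other.  Used to
    compare the probabilistic weighting of the learning rule against a naive
    co-occurrence count on imbalanced association statistics.
    """
    motifs: list[tuple[int, int]] = []
    for pre, post, count in associations:
        motifs.extend([(int(pre), int(post))] * int(count))
    if not motifs:
        raise ValueError("no associations given")
    rng = np.random.default_rng(seed)
    rng.shuffle(motifs)
    n_p = max(1, round(T_p / dt))
    n_gap = round(gap / dt)
    rows: list[np.ndarray] = []
    zero = np.zeros((n_gap, n_units), dtype=bool)
    for pre, post in motifs:
        block = np.zeros((2 * n_p, n_units), dtype=bool)
        block[:n_p, pre] = True
        block[n_p:, post] = True
        rows.append(block)
        rows.append(zero)
    o = np.concatenate(rows[:-1] if n_gap else rows, axis=0)
    return InputSeries(dt=dt, o_clamped=o, total_duration=o.shape[0] * dt)
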