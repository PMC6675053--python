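"""Config-driven experiment runners composing the library modules.

Each experiment kind reproduces one of the model's characterizations:

- ``train``          learn connectivity from a pulse-train protocol
- ``recall``         train then cue sequences, dumping the recalled events
- ``tper-sweep``     measured vs predicted dwell times over a grid of B
- ``noise-sweep``    success rate vs noise level with Wald intervals
- ``sigma50``        stochastic bisection for the 50% noise threshold
- ``overlap-grid``   pairwise-sequence success over (sequential x
                     representational) overlap
- ``disambiguation`` maximum fully-overlapping window vs dwell time

``run_experiment`` validates a flat key-value config, runs the composition
with all randomness seeded, and writes a deterministic directory layout:
a config snapshot, CSV/JSON results and a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .analysis import (
    estimate_success_rate,
    find_sigma50,
    gains_for_sequences,
    max_disambiguation_window,
    persistence_time_from_B,
    summarize_transitions,
    transitions_frame,
)
from .learning import LearningConfig, train_offline
from .network import (
    Connectivity,
    NetworkParams,
    run_recall,
    sequence_chain_connectivity,
)
from .protocols import (
    PatternSet,
    SequenceSpec,
    TrainingProtocol,
    build_input_series,
    make_orthogonal_patterns,
    make_overlapping_pair,
)

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment",
           "measure_chain_persistence"]

logger = logging.getLogger("seqbcpnn")

KINDS = ("train", "recall", "tper-sweep", "noise-sweep", "sigma50",
         "overlap-grid", "disambiguation")

_DEFAULTS: dict[str, Any] = {
    "kind": None,
    "seed": 0,
    "out_dir": "results",
    "fast": False,
    # network
    "H": 1,
    "units_per_hypercolumn": None,   # default: as many as patterns need
    "tau_s_ms": 10.0,
    "tau_a_ms": 250.0,
    "g_a": 1.0,
    "sigma_out": 0.0,
    "dt_ms": 0.5,
    # learning
    "tau_z_pre_ms": 25.0,
    "tau_z_post_ms": 5.0,
    "tau_p_ms": 5000.0,
    "epsilon": 1e-7,
    # protocol
    "T_p_ms": 100.0,
    "IPI_ms": 0.0,
    "epochs": 50,
    "gap_ms": 1000.0,
    "training_dt_ms": 1.0,
    # sequences
    "sequences": [[0, 1, 2, 3, 4]],
    "target_T_per_ms": 100.0,
    "cue_duration_ms": 50.0,
    # sweeps
    "B_grid": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "sigma_grid": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
    "n_trials": 1000,
    "sigma_bracket": [0.0, 3.0],
    "sequential_overlap_grid": None,
    "representational_overlap_grid": None,
    "sequence_length": 10,
    "T_per_grid_ms": [50.0, 100.0, 200.0],
}


class ConfigError(ValueError):
    """Config schema violation; message lists the offending keys."""


@dataclass
class ExperimentConfig:
    """Validated flat experiment configuration (see module docstring)."""

    values: dict[str, Any]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ExperimentConfig":
        unknown = sorted(set(raw) - set(_DEFAULTS))
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        merged = {**_DEFAULTS, **raw}
        bad = []
        if merged["kind"] not in KINDS:
            bad.append(f"kind={merged['kind']!r} (must be one of {KINDS})")
        if not merged["sequences"]:
            bad.append("sequences (empty)")
        for grid_key in ("B_grid", "sigma_grid", "T_per_grid_ms"):
            if not merged[grid_key]:
                bad.append(f"{grid_key} (empty)")
        if bad:
            raise ConfigError("invalid config values: " + "; ".join(bad))
        return cls(values=merged)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @property
    def n_trials(self) -> int:
        n = int(self.values["n_trials"])
        return min(n, 200) if self.values["fast"] else n


def _learning_cfg(cfg: ExperimentConfig) -> LearningConfig:
    return LearningConfig(tau_z_pre=cfg["tau_z_pre_ms"],
                          tau_z_post=cfg["tau_z_post_ms"],
                          tau_p=cfg["tau_p_ms"], epsilon=cfg["epsilon"])


def _protocol(cfg: ExperimentConfig) -> TrainingProtocol:
    return TrainingProtocol(T_p=cfg["T_p_ms"], IPI=cfg["IPI_ms"],
                            epochs=int(cfg["epochs"]),
                            inter_sequence_gap=cfg["gap_ms"])


def _trained_setup(cfg: ExperimentConfig):
    """Patterns, sequences, trained connectivity and recall params."""
    seqs = [SequenceSpec(tuple(s)) for s in cfg["sequences"]]
    n_patterns = max(max(s.pattern_ids) for s in seqs) + 1
    H = int(cfg["H"])
    U = cfg["units_per_hypercolumn"] or n_patterns
    pats = make_orthogonal_patterns(H, int(U), n_patterns)
    series = build_input_series(pats, seqs, _protocol(cfg),
                                dt=cfg["training_dt_ms"])
    conn, traces = train_offline(series, _learning_cfg(cfg))
    params = NetworkParams(H=H, N=pats.n_units, tau_s=cfg["tau_s_ms"],
                           tau_a=cfg["tau_a_ms"], g_a=cfg["g_a"],
                           sigma_out=cfg["sigma_out"], dt=cfg["dt_ms"])
    g_vec = gains_for_sequences(conn, pats, seqs, cfg["target_T_per_ms"], params)
    params = replace(params, g_a=g_vec)
    return pats, seqs, conn, params


def measure_chain_persistence(
    B: float,
    tau_s: float = 10.0,
    tau_a: float = 250.0,
    dt: float = 0.5,
    n_patterns: int = 8,
    sigma_out: float = 0.0,
    seed: int | None = None,
    skip: int = 2,
) -> float:
    """Mean measured dwell time of middle transitions on an idealised chain.

    The chain is handcrafted with equally spaced effective weights
    (w_self - w_next = w_next - w_rest = B, g_a = 1), cued at its head; the
    first ``skip`` events (cue transients) and the terminal event are
    excluded from the mean.
    """
    conn, pats = sequence_chain_connectivity(
        n_patterns, H=1, w_self=1.0, w_next=1.0 - B, w_rest=1.0 - 2 * B)
    params = NetworkParams(H=1, N=n_patterns, tau_s=tau_s, tau_a=tau_a,
                           g_a=1.0, sigma_out=sigma_out, dt=dt)
    T_pred = persistence_time_from_B(B, tau_s, tau_a)
    total = 50.0 + (n_patterns + 1) * T_pred * 1.5 + 200.0
    res = run_recall(conn, params, pats, cue=0, cue_duration=50.0,
                     total_duration=total, seed=seed)
    # first pass through the chain only (free recall wraps around), without
    # the cue-distorted head and the successor-less tail; under noise take
    # each middle pattern's first completed activation
    seen: dict[int, float] = {}
    for e in res.events:
        if skip <= e.pattern_id < n_patterns - 1 and e.pattern_id not in seen:
            seen[e.pattern_id] = e.duration
    if not seen:
        if sigma_out == 0:
            raise RuntimeError(f"no middle events measured at B={B}")
        return float("nan")
    return float(np.mean(list(seen.values())))


# ---------------------------------------------------------------------------
# Experiment kinds
# ---------------------------------------------------------------------------

def _run_train(cfg: ExperimentConfig, out: Path) -> list[str]:
    pats, seqs, conn, params = _trained_setup(cfg)
    conn.save(str(out / "connectivity"), seed=cfg["seed"],
              config={k: cfg[k] for k in ("T_p_ms", "IPI_ms", "epochs",
                                          "tau_z_pre_ms", "tau_z_post_ms")})
    frames = [transitions_frame(summarize_transitions(conn, pats, s, params))
              .assign(sequence=i) for i, s in enumerate(seqs)]
    pd.concat(frames).to_csv(out / "transitions.csv", index=False)
    return ["connectivity.npz", "connectivity.json", "transitions.csv"]


def _run_recall(cfg: ExperimentConfig, out: Path) -> list[str]:
    pats, seqs, conn, params = _trained_setup(cfg)
    results = {}
    for i, seq in enumerate(seqs):
        res = run_recall(conn, params, pats, cue=seq.pattern_ids[0],
                         cue_duration=cfg["cue_duration_ms"],
                         total_duration=cfg["cue_duration_ms"]
                         + 2.5 * (len(seq) + 1) * cfg["target_T_per_ms"],
                         seed=cfg["seed"] + i, target=seq)
        results[f"sequence_{i}"] = res.to_json_dict()
    (out / "recall.json").write_text(json.dumps(results, indent=2))
    return ["recall.json"]


def _run_tper_sweep(cfg: ExperimentConfig, out: Path) -> list[str]:
    rows = []
    for B in cfg["B_grid"]:
        predicted = persistence_time_from_B(B, cfg["tau_s_ms"], cfg["tau_a_ms"])
        measured = measure_chain_persistence(
            B, tau_s=cfg["tau_s_ms"], tau_a=cfg["tau_a_ms"], dt=cfg["dt_ms"],
            sigma_out=cfg["sigma_out"], seed=cfg["seed"])
        rows.append({"B": B, "predicted_ms": predicted, "measured_ms": measured})
        logger.info("B=%.2f predicted=%.1f ms measured=%.1f ms",
                    B, predicted, measured)
    pd.DataFrame(rows).to_csv(out / "tper_sweep.csv", index=False)
    return ["tper_sweep.csv"]


def _run_noise_sweep(cfg: ExperimentConfig, out: Path) -> list[str]:
    pats, seqs, conn, params = _trained_setup(cfg)
    seq = seqs[0]
    rows = []
    ss = np.random.SeedSequence(cfg["seed"])
    for sigma, child in zip(cfg["sigma_grid"],
                            ss.generate_state(len(cfg["sigma_grid"]),
                                              dtype=np.uint32).tolist()):
        est = estimate_success_rate(conn, params, pats, seq, sigma,
                                    cfg.n_trials, seed=child,
                                    cue_duration=cfg["cue_duration_ms"])
        rows.append({"sigma_out": sigma, "p_hat": est.p_hat,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "n_trials": est.n_trials, "seed": child})
        logger.info("sigma=%.2f p_hat=%.3f", sigma, est.p_hat)
    pd.DataFrame(rows).to_csv(out / "noise_sweep.csv", index=False)
    return ["noise_sweep.csv"]


def _run_sigma50(cfg: ExperimentConfig, out: Path) -> list[str]:
    pats, seqs, conn, params = _trained_setup(cfg)
    result = find_sigma50(conn, params, pats, seqs[0],
                          bracket=tuple(cfg["sigma_bracket"]),
                          n_trials=cfg.n_trials, seed=cfg["seed"],
                          cue_duration=cfg["cue_duration_ms"])
    (out / "sigma50.json").write_text(json.dumps(result.to_json_dict(), indent=2))
    return ["sigma50.json"]


def _run_overlap_grid(cfg: ExperimentConfig, out: Path) -> list[str]:
    H = int(cfg["H"])
    length = int(cfg["sequence_length"])
    U = int(cfg["units_per_hypercolumn"] or 2 * length)
    seq_grid = cfg["sequential_overlap_grid"] or list(range(0, length - 1))
    rep_grid = (cfg["representational_overlap_grid"]
                or [k / H for k in range(0, H + 1)])
    rows = []
    for so in seq_grid:
        for ro in rep_grid:
            pset, seqA, seqB = make_overlapping_pair(H, U, length, so, ro)
            series = build_input_series(pset, [seqA, seqB], _protocol(cfg),
                                        dt=cfg["training_dt_ms"])
            # competing sequences need the symmetric batch-average estimator
            conn, _ = train_offline(series, _learning_cfg(cfg),
                                    estimator="average")
            params = NetworkParams(H=H, N=pset.n_units, tau_s=cfg["tau_s_ms"],
                                   tau_a=cfg["tau_a_ms"], dt=cfg["dt_ms"])
            g = gains_for_sequences(conn, pset, [seqA, seqB],
                                    cfg["target_T_per_ms"], params)
            params = replace(params, g_a=g, sigma_out=cfg["sigma_out"])
            ok = True
            for j, seq in enumerate((seqA, seqB)):
                res = run_recall(conn, params, pset, cue=seq.pattern_ids[0],
                                 cue_duration=cfg["cue_duration_ms"],
                                 total_duration=cfg["cue_duration_ms"]
                                 + 2.5 * (length + 1) * cfg["target_T_per_ms"],
                                 seed=cfg["seed"] + j, target=seq)
                ok = ok and bool(res.success)
            rows.append({"sequential_overlap": so,
                         "representational_overlap": ro, "both_recalled": ok})
            logger.info("seq_ov=%d rep_ov=%.2f ok=%s", so, ro, ok)
    pd.DataFrame(rows).to_csv(out / "overlap_grid.csv", index=False)
    return ["overlap_grid.csv"]


def _run_disambiguation(cfg: ExperimentConfig, out: Path) -> list[str]:
    rows = []
    for T_per in cfg["T_per_grid_ms"]:
        best, report = max_disambiguation_window(
            length=int(cfg["sequence_length"]), H=int(cfg["H"]),
            U=int(cfg["units_per_hypercolumn"] or 2 * cfg["sequence_length"]),
            protocol=_protocol(cfg), learning_cfg=_learning_cfg(cfg),
            params=NetworkParams(H=int(cfg["H"]),
                                 N=int(cfg["H"]), tau_s=cfg["tau_s_ms"],
                                 tau_a=cfg["tau_a_ms"], dt=cfg["dt_ms"]),
            target_T_per=T_per, sigma_out=cfg["sigma_out"], seed=cfg["seed"],
            n_trials=cfg.n_trials, cue_duration=cfg["cue_duration_ms"],
            training_dt=cfg["training_dt_ms"])
        rows.append({"target_T_per_ms": T_per, "max_window": best})
        logger.info("T_per=%.0f ms max disambiguation window=%d", T_per, best)
    pd.DataFrame(rows).to_csv(out / "disambiguation.csv", index=False)
    return ["disambiguation.csv"]


_RUNNERS = {
    "train": _run_train,
    "recall": _run_recall,
    "tper-sweep": _run_tper_sweep,
    "noise-sweep": _run_noise_sweep,
    "sigma50": _run_sigma50,
    "overlap-grid": _run_overlap_grid,
    "disambiguation": _run_disambiguation,
}


def run_experiment(config: ExperimentConfig | dict[str, Any]) -> dict[str, Any]:
    """Run one experiment and write its outputs; returns the manifest."""
    if isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.values, indent=2))
    t0 = time.perf_counter()
    files = _RUNNERS[config["kind"]](config, out)
    manifest = {
        "kind": config["kind"],
        "seed": config["seed"],
        "files": ["config.json"] + files,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "version": "0.1.0",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("experiment %s finished in %.1f s", config["kind"],
                manifest["wall_time_s"])
    return manifest
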