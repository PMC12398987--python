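"""The three study experiments and their result bookkeeping.

* training dynamics: one baseline run per training-pool size, keeping the
  full loss curves;
* learning curve: repeated runs of the baseline over a grid of N_cal
  values, each repetition with a fresh random draw from the training pool
  and a fresh initialization;
* architecture comparison: all six architectures at a deliberately small
  N_cal, repeated, feeding the nonparametric group statistics.

Every run's seeds (draw, initialization, shuffling) are derived by
hashing (base_seed, architecture, n_cal, repetition), so any single run
can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .generate import CaseCollection, draw_ncal
from .nn import (
    build_model, train_model, evaluate_model,
    TrainingConfig, TrainingHistory, EvaluationResult,
)

__all__ = [
    "RunResult",
    "derive_seed",
    "run_single",
    "run_training_dynamics",
    "run_size_sweep",
    "run_architecture_comparison",
    "sweep_sizes",
    "accuracy_groups",
    "tidy_results",
    "summarize_results",
    "export_results",
]

#: the 21-point N_cal grid between 50 and 7000 (geometric, rounded)
def sweep_sizes(n_points: int = 21, lo: int = 50, hi: int = 7000) -> list[int]:
    sizes = np.unique(np.rint(np.geomspace(lo, hi, n_points)).astype(int))
    return [int(s) for s in sizes]


@dataclass
class RunResult:
    arch: str
    n_cal: int
    repetition: int
    seed: int
    evaluation: EvaluationResult
    history: TrainingHistory


def derive_seed(base_seed: int, arch: str, n_cal: int, repetition: int,
                role: str) -> int:
    """Stable sub-seed (< 2^31) for one role of one run."""
    key = f"{base_seed}|{arch}|{n_cal}|{repetition}|{role}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def run_single(
    collection: CaseCollection,
    arch: str,
    n_cal: int,
    repetition: int,
    base_seed: int,
    test_eval_n: int | None = None,
    config: TrainingConfig | None = None,
) -> RunResult:
    """One (architecture, N_cal, repetition) training + evaluation run.

    ``arch`` is a preset name (M0..M5) or an ArchitectureSpec.
    ``test_eval_n`` caps the number of held-out test cases scored (the
    first so-many of the frozen test pool); None scores all of them.
    """
    name = arch if isinstance(arch, str) else arch.name
    draw_seed = derive_seed(base_seed, name, n_cal, repetition, "draw")
    init_seed = derive_seed(base_seed, name, n_cal, repetition, "init")
    train_seed = derive_seed(base_seed, name, n_cal, repetition, "train")

    subset = draw_ncal(collection, n_cal, seed=draw_seed)
    model = build_model(arch, seed=init_seed)
    cfg = config or TrainingConfig()
    cfg = TrainingConfig(**{**cfg.__dict__, "seed": train_seed})
    model, history = train_model(model, subset, cfg)

    Xt, yt = collection.testpool.encoded()
    if test_eval_n is not None:
        Xt, yt = Xt[:test_eval_n], yt[:test_eval_n]
    evaluation = evaluate_model(model, (Xt, yt))
    return RunResult(name, n_cal, repetition, init_seed, evaluation, history)


def run_training_dynamics(
    collection: CaseCollection,
    sizes: tuple[int, ...] = (10, 100, 1000, 10000),
    base_seed: int = 0,
    test_eval_n: int | None = 1000,
    arch="M0",
    config: TrainingConfig | None = None,
) -> list[RunResult]:
    """One baseline (M0) run per size, keeping full loss histories."""
    return [run_single(collection, arch, size, 0, base_seed,
                       test_eval_n=test_eval_n, config=config)
            for size in sizes]


def run_size_sweep(
    collection: CaseCollection,
    sizes: list[int] | None = None,
    reps: int = 10,
    base_seed: int = 0,
    arch="M0",
    test_eval_n: int | None = None,
    config: TrainingConfig | None = None,
) -> list[RunResult]:
    """Learning-curve experiment: ``reps`` fresh runs per N_cal value."""
    sizes = sweep_sizes() if sizes is None else sizes
    return [run_single(collection, arch, size, rep, base_seed,
                       test_eval_n=test_eval_n, config=config)
            for size in sizes for rep in range(reps)]


def run_architecture_comparison(
    collection: CaseCollection,
    archs: tuple[str, ...] = ("M0", "M1", "M2", "M3", "M4", "M5"),
    n_cal: int = 300,
    reps: int = 10,
    base_seed: int = 0,
    test_eval_n: int | None = None,
    config: TrainingConfig | None = None,
) -> list[RunResult]:
    """Architecture ablation at one (small) N_cal."""
    return [run_single(collection, arch, n_cal, rep, base_seed,
                       test_eval_n=test_eval_n, config=config)
            for arch in archs for rep in range(reps)]


def accuracy_groups(results: list[RunResult]) -> dict[str, np.ndarray]:
    """Exact-set accuracies grouped by architecture (stats input)."""
    out: dict[str, list[float]] = {}
    for r in results:
        out.setdefault(r.arch, []).append(r.evaluation.exact_set_accuracy)
    return {k: np.array(v) for k, v in out.items()}


def tidy_results(results: list[RunResult]) -> pd.DataFrame:
    """One row per run."""
    return pd.DataFrame([
        {
            "arch": r.arch,
            "n_cal": r.n_cal,
            "repetition": r.repetition,
            "seed": r.seed,
            "exact_set_accuracy": r.evaluation.exact_set_accuracy,
            "per_tooth_accuracy": r.evaluation.per_tooth_accuracy,
            "stopped_epoch": r.history.stopped_epoch,
        }
        for r in results
    ])


def summarize_results(results: list[RunResult]) -> pd.DataFrame:
    """Per-condition mean, sd, and 95% Student-t confidence interval."""
    tidy = tidy_results(results)
    rows = []
    for (arch, n_cal), grp in tidy.groupby(["arch", "n_cal"]):
        acc = grp["exact_set_accuracy"].to_numpy()
        n = len(acc)
        mean = float(acc.mean())
        sd = float(acc.std(ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
        else:
            half = 0.0
        rows.append({
            "arch": arch, "n_cal": n_cal, "n_runs": n,
            "mean_accuracy": mean, "sd_accuracy": sd,
            "ci95_low": mean - half, "ci95_high": mean + half,
        })
    return pd.DataFrame(rows).sort_values(["arch", "n_cal"]).reset_index(drop=True)


def export_results(results: list[RunResult], path_prefix) -> tuple[str, str]:
    """Write tidy and per-condition summary CSVs; returns the two paths."""
    from pathlib import Path

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tidy_path = prefix.with_name(prefix.name + "_runs.csv")
    summary_path = prefix.with_name(prefix.name + "_summary.csv")
    tidy_results(results).to_csv(tidy_path, index=False)
    summarize_results(results).to_csv(summary_path, index=False)
    return str(tidy_path), str(summary_path)
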