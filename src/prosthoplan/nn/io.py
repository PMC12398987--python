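"""Run-directory persistence: weights (.npz), config and history (JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import Sequential
from .presets import ArchitectureSpec, ARCHITECTURES, build_model
from .training import TrainingConfig, TrainingHistory

__all__ = ["save_run", "load_run"]


def save_run(
    run_dir: str | Path,
    model: Sequential,
    arch: ArchitectureSpec | str,
    history: TrainingHistory | None = None,
    config: TrainingConfig | None = None,
) -> Path:
    """Persist a trained model into ``run_dir``; returns the directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    spec = ARCHITECTURES[arch] if isinstance(arch, str) else arch
    weights = {f"w{i:03d}": w for i, w in enumerate(model.get_weights())}
    np.savez(run_dir / "weights.npz", **weights)
    (run_dir / "architecture.json").write_text(json.dumps(asdict(spec), indent=1))
    if config is not None:
        (run_dir / "training_config.json").write_text(
            json.dumps(asdict(config), indent=1))
    if history is not None:
        (run_dir / "history.json").write_text(json.dumps(asdict(history), indent=1))
    return run_dir


def load_run(run_dir: str | Path) -> tuple[Sequential, ArchitectureSpec]:
    """Rebuild the model saved by :func:`save_run`."""
    run_dir = Path(run_dir)
    spec_dict = json.loads((run_dir / "architecture.json").read_text())
    spec_dict["dense_widths"] = tuple(spec_dict["dense_widths"])
    spec = ArchitectureSpec(**spec_dict)
    model = build_model(spec, seed=0)
    with np.load(run_dir / "weights.npz") as npz:
        weights = [npz[k] for k in sorted(npz.files)]
    model.set_weights(weights)
    return model, spec
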