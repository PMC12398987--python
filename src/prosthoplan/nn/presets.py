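"""The six benchmark architectures (M0..M5) and the model builder.

M0 is the baseline: Embedding(64) > bidirectional LSTM(128 per
direction) > Dropout(0.5) > Dense(64, ReLU) > Dropout(0.5) > Dense(4,
softmax), applied position-wise over the 16 teeth.  The variants:

* M1 — the LSTM replaced by a position-wise Dense(128): no layer can see
  other teeth, so per-position outputs are independent of the rest of the
  chart (the structural reason it collapses on this task);
* M2 — M0 plus an extra Dense(32)+Dropout;
* M3 — M0 without its Dense(64);
* M4 — all widths doubled (embedding included);
* M5 — all widths halved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chart import FINDING_CODES, PLAN_CODES
from .layers import Embedding, Dense, BiLSTM, Dropout
from .model import Sequential

__all__ = ["ArchitectureSpec", "ARCHITECTURES", "build_model"]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one sequence-classification network.

    ``recurrent_units`` is the LSTM width per direction; 0 means the
    recurrent layer is replaced by a position-wise dense layer whose width
    is then the first entry of ``dense_widths``.
    """

    name: str
    embedding_dim: int
    recurrent_units: int
    dense_widths: tuple[int, ...]
    dropout_rate: float = 0.5
    bidirectional: bool = True
    output_classes: int = len(PLAN_CODES)

    def __post_init__(self):
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.recurrent_units < 0:
            raise ValueError("recurrent_units must be >= 0")
        if self.recurrent_units == 0 and not self.dense_widths:
            raise ValueError(
                "a non-recurrent architecture needs at least one dense layer")
        if any(w <= 0 for w in self.dense_widths):
            raise ValueError("dense widths must be positive")


ARCHITECTURES: dict[str, ArchitectureSpec] = {
    "M0": ArchitectureSpec("M0", 64, 128, (64,)),
    "M1": ArchitectureSpec("M1", 64, 0, (128, 64)),
    "M2": ArchitectureSpec("M2", 64, 128, (64, 32)),
    "M3": ArchitectureSpec("M3", 64, 128, ()),
    "M4": ArchitectureSpec("M4", 128, 256, (128,)),
    "M5": ArchitectureSpec("M5", 32, 64, (32,)),
}


def build_model(spec: ArchitectureSpec | str, seed: int) -> Sequential:
    """Build an untrained network; weight initialization is seeded."""
    if isinstance(spec, str):
        spec = ARCHITECTURES[spec]
    rng = np.random.default_rng(seed)
    layers = [Embedding(len(FINDING_CODES), spec.embedding_dim, rng)]
    width = spec.embedding_dim
    if spec.recurrent_units > 0:
        if not spec.bidirectional:
            raise ValueError("only bidirectional recurrent layers are supported")
        layers.append(BiLSTM(width, spec.recurrent_units, rng))
        width = 2 * spec.recurrent_units
        layers.append(Dropout(spec.dropout_rate))
    for w in spec.dense_widths:
        layers.append(Dense(width, w, rng, activation="relu"))
        layers.append(Dropout(spec.dropout_rate))
        width = w
    layers.append(Dense(width, spec.output_classes, rng, activation="linear"))
    return Sequential(layers)
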