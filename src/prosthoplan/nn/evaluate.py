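"""Scoring trained planners against the rule-engine labels.

The headline metric is exact-set accuracy: the percentage of test cases
whose full 16-position predicted plan matches the labelled plan at every
position.  Per-tooth accuracy (over all 16 x n positions) and a 4x4
per-tooth confusion matrix over the plan codes are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..chart import FindingsChart, PlanChart, PLAN_CODES, N_TEETH, \
    encode_findings, decode_plan
from ..generate import CaseCollection
from .model import Sequential

__all__ = ["EvaluationResult", "evaluate_model", "predict_plan"]


@dataclass(frozen=True)
class EvaluationResult:
    exact_set_accuracy: float     # % of cases fully correct
    per_tooth_accuracy: float     # % of positions correct
    n_cases: int
    confusion: np.ndarray         # (4,4) counts, rows=true, cols=predicted


def evaluate_model(
    model: Sequential,
    cases: CaseCollection | tuple[np.ndarray, np.ndarray],
) -> EvaluationResult:
    """Score a model on labelled cases; raises on an empty case set."""
    if isinstance(cases, CaseCollection):
        X, y = cases.encoded()
    else:
        X, y = (np.asarray(a) for a in cases)
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot evaluate on an empty case set")

    pred = model.predict_labels(X)
    hits = pred == y
    exact = 100.0 * float(hits.all(axis=1).mean())
    per_tooth = 100.0 * float(hits.mean())
    k = len(PLAN_CODES)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (y.ravel(), pred.ravel()), 1)
    return EvaluationResult(exact, per_tooth, n, confusion)


def predict_plan(model: Sequential, findings: FindingsChart) -> PlanChart:
    """Predicted plan chart for one findings chart (argmax per tooth)."""
    x = encode_findings(findings)[None, :]
    probs = model.predict_proba(x)[0]
    assert probs.shape == (N_TEETH, len(PLAN_CODES))
    return decode_plan(probs)
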