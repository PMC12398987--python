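"""Tooth-chart data model: vocabularies, parsing, and numeric encodings.

A single jaw is modelled as 16 ordered tooth positions (FDI two-digit
labels 18..11, 21..28 attached for display).  A findings chart assigns one
of ten per-tooth findings to every position; a plan chart assigns one of
four prosthesis choices.  Both vocabularies follow the German standard-care
treatment-plan abbreviations.

The integer index of every symbol is fixed (vocabulary row order) so that
encodings, and any file that embeds them, are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FINDING_CODES",
    "PLAN_CODES",
    "FINDING_INDEX",
    "PLAN_INDEX",
    "TOOTH_POSITIONS",
    "ToothPosition",
    "FindingsChart",
    "PlanChart",
    "parse_chart",
    "format_chart",
    "encode_findings",
    "decode_findings",
    "encode_plan",
    "decode_plan",
    "vocabulary_tables",
]

N_TEETH = 16


@dataclass(frozen=True)
class FindingCode:
    symbol: str
    meaning: str


@dataclass(frozen=True)
class PlanCode:
    symbol: str
    meaning: str


#: The ten per-tooth findings, in fixed index order.
FINDING_CODES: tuple[FindingCode, ...] = (
    FindingCode("f", "missing tooth, not replaced by FDP or RDP"),
    FindingCode(".", "tooth, sufficient"),
    FindingCode("x", "tooth to be extracted (condemned)"),
    FindingCode("k", "crown, sufficient (FDP)"),
    FindingCode("b", "bridge unit, sufficient (FDP)"),
    FindingCode("e", "replaced tooth with RDP, sufficient"),
    FindingCode("ww", "insufficient natural tooth, preservation worthy"),
    FindingCode("kw", "insufficient crown, renewal required (FDP)"),
    FindingCode("bw", "insufficient bridge unit, renewal required (FDP)"),
    FindingCode("ew", "insufficiently replaced tooth with RDP, renewal required"),
)

#: The four prosthesis choices, in fixed index order.
PLAN_CODES: tuple[PlanCode, ...] = (
    PlanCode("-", "no dental prosthesis required"),
    PlanCode("K", "crown"),
    PlanCode("B", "bridge unit"),
    PlanCode("E", "tooth to be replaced with RDP"),
)

FINDING_INDEX: dict[str, int] = {c.symbol: i for i, c in enumerate(FINDING_CODES)}
PLAN_INDEX: dict[str, int] = {c.symbol: i for i, c in enumerate(PLAN_CODES)}

FINDING_SYMBOLS: tuple[str, ...] = tuple(c.symbol for c in FINDING_CODES)
PLAN_SYMBOLS: tuple[str, ...] = tuple(c.symbol for c in PLAN_CODES)


@dataclass(frozen=True)
class ToothPosition:
    """One of the 16 slots of a single jaw.

    ``index`` runs 1..16 left-to-right; the FDI label is display-only (all
    planning rules operate on positions).  Positions 1 and 16 are the
    wisdom teeth.
    """

    index: int
    fdi_label: str
    is_wisdom: bool


_FDI_UPPER = ["18", "17", "16", "15", "14", "13", "12", "11",
              "21", "22", "23", "24", "25", "26", "27", "28"]

TOOTH_POSITIONS: tuple[ToothPosition, ...] = tuple(
    ToothPosition(i + 1, _FDI_UPPER[i], i in (0, N_TEETH - 1)) for i in range(N_TEETH)
)

WISDOM_POSITIONS = frozenset({1, N_TEETH})


def is_wisdom(position: int) -> bool:
    """True for the two terminal (wisdom-tooth) positions, 1-based."""
    return position in WISDOM_POSITIONS


class _Chart:
    """Immutable 16-symbol chart; subclasses fix the vocabulary."""

    _index: dict[str, int] = {}
    _kind: str = ""

    __slots__ = ("entries",)

    def __init__(self, entries: Iterable[str]):
        entries = tuple(entries)
        if len(entries) != N_TEETH:
            raise ValueError(
                f"a {self._kind} chart needs exactly {N_TEETH} entries, got {len(entries)}"
            )
        for pos, sym in enumerate(entries, start=1):
            if sym not in self._index:
                raise ValueError(
                    f"unknown {self._kind} symbol {sym!r} at position {pos}"
                )
        object.__setattr__(self, "entries", entries)

    def __setattr__(self, name, value):  # immutability
        raise AttributeError(f"{type(self).__name__} is immutable")

    def __reduce__(self):  # pickle support despite blocked __setattr__
        return (type(self), (self.entries,))

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return N_TEETH

    def __getitem__(self, i):
        return self.entries[i]

    def __eq__(self, other) -> bool:
        return type(other) is type(self) and other.entries == self.entries

    def __hash__(self) -> int:
        return hash((type(self).__name__, self.entries))

    def __repr__(self) -> str:
        return f"{type(self).__name__}({' '.join(self.entries)!r})"

    def __str__(self) -> str:
        return " ".join(self.entries)


class FindingsChart(_Chart):
    """Ordered 16-token vector of finding symbols (the planner/ANN input)."""

    _index = FINDING_INDEX
    _kind = "finding"


class PlanChart(_Chart):
    """Ordered 16-token vector of plan symbols (the planner/ANN output)."""

    _index = PLAN_INDEX
    _kind = "plan"


def parse_chart(tokens: str | Sequence[str], vocabulary: str) -> FindingsChart | PlanChart:
    """Parse 16 whitespace- or comma-separated tokens into a chart.

    ``vocabulary`` is ``"finding"`` or ``"plan"``.  Raises ``ValueError``
    naming the offending token and position for unknown symbols, or the
    token count for wrong-length input.
    """
    if isinstance(tokens, str):
        tokens = tokens.replace(",", " ").split()
    tokens = list(tokens)
    if vocabulary == "finding":
        return FindingsChart(tokens)
    if vocabulary == "plan":
        return PlanChart(tokens)
    raise ValueError(f"vocabulary must be 'finding' or 'plan', got {vocabulary!r}")


def format_chart(chart: _Chart) -> str:
    """16 tokens joined by single spaces; inverse of :func:`parse_chart`."""
    return str(chart)


def encode_findings(chart: FindingsChart) -> np.ndarray:
    """Findings chart -> length-16 integer index vector (the ANN input)."""
    return np.array([FINDING_INDEX[s] for s in chart], dtype=np.int64)


def decode_findings(indices: Sequence[int]) -> FindingsChart:
    """Inverse of :func:`encode_findings`."""
    return FindingsChart(FINDING_SYMBOLS[int(i)] for i in indices)


def encode_plan(chart: PlanChart) -> np.ndarray:
    """Plan chart -> 16x4 one-hot matrix (the training target)."""
    out = np.zeros((N_TEETH, len(PLAN_CODES)), dtype=np.float64)
    for row, sym in enumerate(chart):
        out[row, PLAN_INDEX[sym]] = 1.0
    return out


def decode_plan(probabilities: np.ndarray, tol: float = 1e-6) -> PlanChart:
    """16x4 row-stochastic matrix -> plan chart by per-row argmax.

    Each row must sum to 1 within ``tol``.  Ties break toward the lowest
    index, so the prediction is deterministic.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.shape != (N_TEETH, len(PLAN_CODES)):
        raise ValueError(
            f"expected a {N_TEETH}x{len(PLAN_CODES)} matrix, got {probabilities.shape}"
        )
    sums = probabilities.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > tol)[0]
    if bad.size:
        raise ValueError(
            f"row {bad[0] + 1} sums to {sums[bad[0]]:.8f}, not 1 within {tol}"
        )
    return PlanChart(PLAN_SYMBOLS[i] for i in probabilities.argmax(axis=1))


def decode_plan_indices(indices: Sequence[int]) -> PlanChart:
    """Length-16 plan index vector -> plan chart."""
    return PlanChart(PLAN_SYMBOLS[int(i)] for i in indices)


def vocabulary_tables() -> dict:
    """Serializable symbol->index tables, embedded in every dataset file."""
    return {"finding": dict(FINDING_INDEX), "plan": dict(PLAN_INDEX)}
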