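"""Deterministic standard-care prosthesis planner and structural validator.

The planner maps a 16-position findings chart to a plan chart under the
German standard-care rules for a single jaw:

* pontics must be flanked by crowned abutments on both sides (no
  cantilever bridges);
* within one fixed dental prosthesis (FDP: a crown/bridge block) the
  sufficiency state is uniform — a bridge is renewed as a whole or not at
  all;
* the teeth replaced by a removable dental prosthesis (RDP) are either all
  sufficient or all due for renewal;
* missing wisdom teeth are never replaced;
* four or more teeth to replace, a gap that cannot be bridged, or an RDP
  due for renewal all force the removable pathway.

``plan_case`` is a pure function: it is the ground-truth labelling oracle
for the synthetic data and the reference against which trained networks
are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chart import FindingsChart, PlanChart, N_TEETH, is_wisdom

__all__ = [
    "Violation",
    "GapSegment",
    "validate_findings",
    "find_gaps",
    "count_replacement_needs",
    "requires_rdp",
    "plan_case",
    "plan_case_explained",
    "plan_contains_fdp",
]

GAP = frozenset({"f", "x"})
PONTIC = frozenset({"b", "bw"})
CROWN = frozenset({"k", "kw"})
FDP_UNITS = CROWN | PONTIC
RDP_UNITS = frozenset({"e", "ew"})
SUFFICIENT_FDP = frozenset({"k", "b"})
INSUFFICIENT_FDP = frozenset({"kw", "bw"})
#: teeth that can anchor a new bridge: natural teeth (sufficient or
#: preservation-worthy) and crowns (sufficient or due for renewal) - but
#: not crowns already serving as abutments of an existing bridge (see
#: :func:`_bridge_member_positions`): existing bridges are left untouched,
#: so gaps beside them go the removable route via unboundedness
CROWNABLE = frozenset({".", "ww", "k", "kw"})


@dataclass(frozen=True)
class Violation:
    """One structural rule broken by a findings chart."""

    rule_id: str          # "R1" | "R2" | "R3"
    positions: tuple[int, ...]  # 1-based positions involved
    message: str


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of missing/condemned teeth (1-based inclusive span)."""

    start: int
    end: int
    causes: tuple[str, ...]   # per-position finding, "f" or "x"
    bounded_left: bool        # a crownable tooth sits immediately left
    bounded_right: bool
    wisdom_only: bool         # every position in the run is a wisdom slot

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


def _runs(symbols: tuple[str, ...], members: frozenset) -> list[tuple[int, int]]:
    """Maximal runs (1-based inclusive) of positions whose symbol is in members."""
    runs, start = [], None
    for pos in range(1, N_TEETH + 1):
        if symbols[pos - 1] in members:
            if start is None:
                start = pos
        elif start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, N_TEETH))
    return runs


def validate_findings(chart: FindingsChart) -> list[Violation]:
    """Check the three structural constraints; empty list means valid.

    R1: every maximal pontic run (b/bw) is flanked by crowns (k/kw) on
    both sides.  R2: each FDP block containing a pontic has uniform
    sufficiency.  R3: RDP-replaced teeth are uniformly e or uniformly ew.
    """
    s = chart.entries
    out: list[Violation] = []

    for start, end in _runs(s, PONTIC):
        left_ok = start > 1 and s[start - 2] in CROWN
        right_ok = end < N_TEETH and s[end] in CROWN
        if not (left_ok and right_ok):
            out.append(Violation(
                "R1", tuple(range(start, end + 1)),
                f"pontic run at positions {start}..{end} is not flanked by "
                f"crowns on both sides",
            ))

    for start, end in _runs(s, FDP_UNITS):
        block = s[start - 1:end]
        if not any(sym in PONTIC for sym in block):
            continue  # isolated crowns carry no uniformity constraint
        if not (all(sym in SUFFICIENT_FDP for sym in block)
                or all(sym in INSUFFICIENT_FDP for sym in block)):
            out.append(Violation(
                "R2", tuple(range(start, end + 1)),
                f"FDP at positions {start}..{end} mixes sufficient and "
                f"insufficient units",
            ))

    e_pos = tuple(p for p in range(1, N_TEETH + 1) if s[p - 1] == "e")
    ew_pos = tuple(p for p in range(1, N_TEETH + 1) if s[p - 1] == "ew")
    if e_pos and ew_pos:
        out.append(Violation(
            "R3", e_pos + ew_pos,
            "RDP-replaced teeth mix sufficient (e) and renewal-required (ew)",
        ))
    return out


def _bridge_member_positions(chart: FindingsChart) -> frozenset[int]:
    """Positions inside FDP blocks that contain at least one pontic."""
    members: set[int] = set()
    for start, end in _runs(chart.entries, FDP_UNITS):
        if any(sym in PONTIC for sym in chart.entries[start - 1:end]):
            members.update(range(start, end + 1))
    return frozenset(members)


def _can_anchor(chart: FindingsChart, pos: int,
                bridge_members: frozenset[int]) -> bool:
    return chart[pos - 1] in CROWNABLE and pos not in bridge_members


def find_gaps(chart: FindingsChart) -> list[GapSegment]:
    """Maximal runs of missing (f) or condemned (x) teeth, annotated."""
    s = chart.entries
    members = _bridge_member_positions(chart)
    out = []
    for start, end in _runs(s, GAP):
        out.append(GapSegment(
            start=start,
            end=end,
            causes=tuple(s[start - 1:end]),
            bounded_left=start > 1 and _can_anchor(chart, start - 1, members),
            bounded_right=end < N_TEETH and _can_anchor(chart, end + 1, members),
            wisdom_only=all(is_wisdom(p) for p in range(start, end + 1)),
        ))
    return out


def _effective_gaps(chart: FindingsChart) -> list[GapSegment]:
    """Gap segments with wisdom positions trimmed off the jaw ends.

    A missing wisdom tooth needs no replacement, so it neither counts
    toward the replacement threshold nor participates in boundedness.
    """
    s = chart.entries
    members = _bridge_member_positions(chart)
    out = []
    for seg in find_gaps(chart):
        start, end = seg.start, seg.end
        if start == 1 and is_wisdom(1):
            start += 1
        if end == N_TEETH:
            end -= 1
        if start > end:
            continue
        out.append(GapSegment(
            start=start,
            end=end,
            causes=tuple(s[start - 1:end]),
            bounded_left=start > 1 and _can_anchor(chart, start - 1, members),
            bounded_right=end < N_TEETH and _can_anchor(chart, end + 1, members),
            wisdom_only=False,
        ))
    return out


def count_replacement_needs(chart: FindingsChart) -> int:
    """Number of non-wisdom positions that are missing or condemned."""
    return sum(
        1 for p in range(1, N_TEETH + 1)
        if chart[p - 1] in GAP and not is_wisdom(p)
    )


def requires_rdp(chart: FindingsChart) -> tuple[bool, str | None]:
    """Whether any replacement must go onto a removable prosthesis.

    True when (a) four or more teeth need replacement, (b) some gap cannot
    be bridged because it lacks a crownable abutment on one side (no
    cantilever bridges), or (c) an existing RDP is due for renewal (ew),
    which forces the removable pathway.  Returns (flag, reason) with
    reason one of ">=4", "unbounded gap", "rdp renewal", or None.
    """
    if count_replacement_needs(chart) >= 4:
        return True, ">=4"
    for seg in _effective_gaps(chart):
        if not (seg.bounded_left and seg.bounded_right):
            return True, "unbounded gap"
    if "ew" in chart.entries:
        return True, "rdp renewal"
    return False, None


def plan_case_explained(chart: FindingsChart) -> tuple[PlanChart, tuple[str, ...]]:
    """Plan a findings chart; also return the rule fired per position.

    Per-position rules: P1 missing wisdom tooth left untreated; P2
    removable pathway (gap/RDP tooth goes onto the denture); P3 new bridge
    (pontic B with flanking abutments K); P4 renewal of insufficient fixed
    work (kw->K, bw->B); P5 insufficient preservation-worthy tooth crowned
    (ww->K); P6 nothing required.
    """
    violations = validate_findings(chart)
    if violations:
        raise ValueError(
            "cannot plan a structurally invalid chart: "
            + "; ".join(f"{v.rule_id}: {v.message}" for v in violations)
        )
    s = chart.entries
    plan = ["-"] * N_TEETH
    why = ["P6"] * N_TEETH

    rdp, _reason = requires_rdp(chart)

    for p in range(1, N_TEETH + 1):
        if s[p - 1] in GAP and is_wisdom(p):
            why[p - 1] = "P1"  # missing wisdom tooth: no replacement

    if rdp:
        for p in range(1, N_TEETH + 1):
            sym = s[p - 1]
            if sym in GAP and not is_wisdom(p):
                plan[p - 1], why[p - 1] = "E", "P2"
            elif sym == "ew":
                plan[p - 1], why[p - 1] = "E", "P2"
            elif sym == "e":
                # the denture is renewed or extended, taking the
                # already-replaced teeth with it
                plan[p - 1], why[p - 1] = "E", "P2"
    else:
        for seg in _effective_gaps(chart):
            for p in seg.positions:
                plan[p - 1], why[p - 1] = "B", "P3"
            for p in (seg.start - 1, seg.end + 1):
                if s[p - 1] in {".", "k"}:  # ww/kw get K below anyway
                    plan[p - 1], why[p - 1] = "K", "P3"

    for p in range(1, N_TEETH + 1):
        sym = s[p - 1]
        if sym == "kw":
            plan[p - 1], why[p - 1] = "K", "P4"
        elif sym == "bw":
            plan[p - 1], why[p - 1] = "B", "P4"
        elif sym == "ww":
            plan[p - 1], why[p - 1] = "K", "P5"

    return PlanChart(plan), tuple(why)


def plan_case(chart: FindingsChart) -> PlanChart:
    """Deterministic standard-care plan for a valid findings chart."""
    return plan_case_explained(chart)[0]


def plan_contains_fdp(plan: PlanChart) -> bool:
    """True iff the plan places at least one bridge unit (B)."""
    return "B" in plan.entries
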