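"""Constructive generator of valid, unique, rule-labelled dental cases.

Charts are built constructively rather than by pure rejection: the
removable prosthesis (if any) is placed first with uniform sufficiency,
then missing/condemned teeth, then crown/bridge work on eligible spans,
then insufficient-but-preservation-worthy teeth, so every draw satisfies
the structural constraints by construction.  Every second generated case
is forced (by bounded rejection) to contain a bridge unit in its plan,
which keeps fixed prostheses well represented; under the unforced rules
they would be comparatively rare.

Each case is labelled by the deterministic planner, the full collection
is deduplicated on the findings chart, and a fixed-size test pool is
frozen into the file at generation time so that no test case can leak
into training.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chart import (
    FindingsChart, PlanChart, N_TEETH, FINDING_INDEX, PLAN_INDEX,
    encode_findings, vocabulary_tables, is_wisdom,
)
from .rules import plan_case, validate_findings, plan_contains_fdp

__all__ = [
    "GeneratorConfig",
    "CasePair",
    "CaseCollection",
    "sample_findings",
    "generate_collection",
    "draw_ncal",
    "write_collection",
    "read_collection",
]

_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling-law parameters for the synthetic study population.

    ``n_total``/``n_test`` mirror the study design (20,000 cases, half
    reserved for testing).  The nuisance parameters shape the findings
    distribution: ``max_missing`` bounds the per-case count of
    missing/condemned teeth (drawn uniformly on 0..max_missing),
    ``p_insufficient`` is the per-appliance probability that an FDP or
    RDP is due for renewal, ``p_rdp_present`` the probability that the
    case already wears a removable prosthesis, and ``p_ww`` the per-tooth
    rate of insufficient-but-preservation-worthy natural teeth.
    """

    n_total: int = 20_000
    n_test: int = 10_000
    seed: int = 0
    max_missing: int = 10
    p_insufficient: float = 0.5
    p_rdp_present: float = 0.3
    p_ww: float = 0.1
    p_complete_denture: float = 0.15  # given an RDP is present
    p_bridge_per_span: float = 0.4    # place a bridge in an eligible free span
    p_lone_crown: float = 0.1         # isolated crown on a remaining tooth

    def __post_init__(self):
        if not (0 < self.n_test < self.n_total):
            raise ValueError("need 0 < n_test < n_total")
        for name in ("p_insufficient", "p_rdp_present", "p_ww",
                     "p_complete_denture", "p_bridge_per_span", "p_lone_crown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class CasePair:
    findings: FindingsChart
    plan: PlanChart
    case_id: int


@dataclass
class CaseCollection:
    """Deduplicated findings/plan pairs with a frozen train/test split."""

    cases: list[CasePair]
    split: list[str]                  # "trainpool" | "test", parallel to cases
    config: GeneratorConfig | None = None
    index_tables: dict = field(default_factory=vocabulary_tables)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def subset(self, indices) -> "CaseCollection":
        return CaseCollection(
            cases=[self.cases[i] for i in indices],
            split=[self.split[i] for i in indices],
            config=self.config,
            index_tables=self.index_tables,
        )

    def pool(self, name: str) -> "CaseCollection":
        """The trainpool or test sub-collection."""
        return self.subset([i for i, s in enumerate(self.split) if s == name])

    @property
    def trainpool(self) -> "CaseCollection":
        return self.pool("trainpool")

    @property
    def testpool(self) -> "CaseCollection":
        return self.pool("test")

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): integer findings (n,16) and integer plan labels (n,16)."""
        n = len(self.cases)
        X = np.empty((n, N_TEETH), dtype=np.int64)
        y = np.empty((n, N_TEETH), dtype=np.int64)
        for i, case in enumerate(self.cases):
            X[i] = encode_findings(case.findings)
            y[i] = [PLAN_INDEX[s] for s in case.plan]
        return X, y


def _free_runs(taken: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs (1-based inclusive) of untouched positions."""
    runs, start = [], None
    for pos in range(1, N_TEETH + 1):
        if not taken[pos - 1]:
            if start is None:
                start = pos
        elif start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, N_TEETH))
    return runs


def _sample_once(rng: np.random.Generator, cfg: GeneratorConfig) -> FindingsChart:
    """One constructive draw; always structurally valid."""
    sym = ["."] * N_TEETH
    taken = [False] * N_TEETH
    non_wisdom = [p for p in range(1, N_TEETH + 1) if not is_wisdom(p)]

    # 1) removable prosthesis: all-or-none sufficiency, never on wisdom slots
    if rng.random() < cfg.p_rdp_present:
        if rng.random() < cfg.p_complete_denture:
            replaced = list(non_wisdom)
        else:
            k = int(rng.integers(1, 7))
            replaced = list(rng.choice(non_wisdom, size=k, replace=False))
        code = "ew" if rng.random() < cfg.p_insufficient else "e"
        for p in replaced:
            sym[p - 1] = code
            taken[p - 1] = True

    # 2) missing / condemned teeth
    m = int(rng.integers(0, cfg.max_missing + 1))
    free = [p for p in range(1, N_TEETH + 1) if not taken[p - 1]]
    m = min(m, len(free))
    if m:
        for p in rng.choice(free, size=m, replace=False):
            sym[p - 1] = "x" if rng.random() < 0.5 else "f"
            taken[p - 1] = True

    # 3) bridges on eligible spans (abutment-pontic(s)-abutment, length>=3)
    for start, end in _free_runs(taken):
        run_len = end - start + 1
        if run_len < 3 or rng.random() >= cfg.p_bridge_per_span:
            continue
        pontics = int(rng.integers(1, min(3, run_len - 2) + 1))
        span = pontics + 2
        offset = int(rng.integers(0, run_len - span + 1))
        s0 = start + offset
        bad = rng.random() < cfg.p_insufficient
        crown, unit = ("kw", "bw") if bad else ("k", "b")
        for p in range(s0, s0 + span):
            sym[p - 1] = crown if p in (s0, s0 + span - 1) else unit
            taken[p - 1] = True

    # 4) lone crowns, kept off FDP neighbours so blocks stay uniform
    for p in range(1, N_TEETH + 1):
        if taken[p - 1]:
            continue
        neighbours = [sym[q - 1] for q in (p - 1, p + 1) if 1 <= q <= N_TEETH]
        if any(s in ("k", "b", "kw", "bw") for s in neighbours):
            continue
        if rng.random() < cfg.p_lone_crown:
            sym[p - 1] = "kw" if rng.random() < cfg.p_insufficient else "k"
            taken[p - 1] = True

    # 5) insufficient preservation-worthy teeth on the rest
    for p in range(1, N_TEETH + 1):
        if not taken[p - 1] and rng.random() < cfg.p_ww:
            sym[p - 1] = "ww"

    return FindingsChart(sym)


def sample_findings(
    rng: np.random.Generator,
    force_fdp_in_plan: bool = False,
    config: GeneratorConfig | None = None,
) -> FindingsChart:
    """Draw one valid findings chart.

    With ``force_fdp_in_plan`` the draw is repeated (bounded rejection)
    until the planned treatment contains at least one bridge unit.
    """
    cfg = config or GeneratorConfig()
    for _ in range(_MAX_ATTEMPTS):
        chart = _sample_once(rng, cfg)
        if validate_findings(chart):  # pragma: no cover - constructive guarantee
            continue
        if not force_fdp_in_plan or plan_contains_fdp(plan_case(chart)):
            return chart
    raise RuntimeError(
        f"no admissible chart found in {_MAX_ATTEMPTS} attempts; "
        "the generator configuration is too restrictive"
    )


def generate_collection(config: GeneratorConfig | None = None) -> CaseCollection:
    """Generate ``n_total`` unique labelled cases with a frozen test split.

    Cases at even generation ranks (0, 2, 4, ...) are forced to contain a
    bridge in their plan; duplicates are resampled at the same rank so the
    forcing parity is preserved exactly.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    seen: set[tuple[str, ...]] = set()
    cases: list[CasePair] = []
    for rank in range(cfg.n_total):
        force = rank % 2 == 0
        for _ in range(_MAX_ATTEMPTS):
            chart = sample_findings(rng, force_fdp_in_plan=force, config=cfg)
            if chart.entries not in seen:
                break
        else:  # pragma: no cover
            raise RuntimeError(
                f"could not find a new unique chart at rank {rank}; "
                "state space exhausted under this configuration"
            )
        seen.add(chart.entries)
        cases.append(CasePair(chart, plan_case(chart), case_id=rank))

    split = ["trainpool"] * cfg.n_total
    for i in rng.choice(cfg.n_total, size=cfg.n_test, replace=False):
        split[i] = "test"
    return CaseCollection(cases=cases, split=split, config=cfg)


def draw_ncal(collection: CaseCollection, n_cal: int, seed: int) -> CaseCollection:
    """Uniform random draw of ``n_cal`` cases from the trainpool only."""
    pool = collection.trainpool
    if n_cal > len(pool):
        raise ValueError(f"n_cal={n_cal} exceeds trainpool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_cal, replace=False)
    return pool.subset(idx)


# ---------------------------------------------------------------------------
# File I/O: CSV with a JSON sidecar carrying config, seed and vocabularies.

_HEADER = (["case_id", "split"]
           + [f"f{i:02d}" for i in range(1, N_TEETH + 1)]
           + [f"p{i:02d}" for i in range(1, N_TEETH + 1)])


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_collection(collection: CaseCollection, path: str | Path) -> None:
    """Write the collection as CSV plus a ``*.meta.json`` sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for case, split in zip(collection.cases, collection.split):
            w.writerow([case.case_id, split,
                        *case.findings.entries, *case.plan.entries])
    meta = {
        "config": asdict(collection.config) if collection.config else None,
        "index_tables": collection.index_tables,
        "n_cases": len(collection),
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_collection(path: str | Path) -> CaseCollection:
    """Lossless inverse of :func:`write_collection`."""
    path = Path(path)
    meta_file = _meta_path(path)
    config = None
    index_tables = vocabulary_tables()
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        if meta.get("index_tables") is not None:
            stored = meta["index_tables"]
            if (stored.get("finding") != dict(FINDING_INDEX)
                    or stored.get("plan") != dict(PLAN_INDEX)):
                raise ValueError(
                    f"{meta_file} embeds vocabulary index tables that do not "
                    "match this package's vocabularies"
                )
        if meta.get("config"):
            config = GeneratorConfig(**meta["config"])

    cases, split = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _HEADER:
            got = 0 if header is None else len(header)
            raise ValueError(
                f"{path}: expected {len(_HEADER)} columns "
                f"({_HEADER[0]},...), got {got}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_HEADER):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_HEADER)} fields, "
                    f"got {len(row)}"
                )
            case_id = int(row[0])
            if row[1] not in ("trainpool", "test"):
                raise ValueError(f"{path}:{lineno}: unknown split {row[1]!r}")
            try:
                findings = FindingsChart(row[2:2 + N_TEETH])
                plan = PlanChart(row[2 + N_TEETH:2 + 2 * N_TEETH])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            cases.append(CasePair(findings, plan, case_id))
            split.append(row[1])
    return CaseCollection(cases=cases, split=split, config=config,
                          index_tables=index_tables)
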