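"""Alignment-based conformance checking against the sequential pathway.

Each trace is aligned optimally against the normative activity chain using
synchronous moves (label matches), log-only moves (observed but not expected
here) and model-only moves (expected but not observed).  Because the model is
strictly sequential, optimal alignment reduces to an edit distance with
matches and indels only, solved by dynamic programming.  The alignments feed
the replay-fitness and escaping-edges precision metrics and a rule-based
deviation classifier with root-cause mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .event_log import EventLog, Trace
from .normative_model import NormativeModel

__all__ = [
    "Alignment",
    "Move",
    "ConformanceMetrics",
    "DeviationRecord",
    "DeviationSummary",
    "DEFAULT_ROOT_CAUSE_RULES",
    "align_trace",
    "align_log",
    "trace_fitness",
    "log_fitness",
    "log_precision",
    "backwards_precision",
    "combined_metrics",
    "structural_metrics",
    "classify_deviations",
    "deviation_summary",
    "records_to_frame",
]

SYNC = "sync"
LOG_ONLY = "log_only"
MODEL_ONLY = "model_only"

DEFAULT_COSTS: Mapping[str, float] = {SYNC: 0.0, LOG_ONLY: 1.0, MODEL_ONLY: 1.0}


@dataclass(frozen=True)
class Move:
    kind: str
    activity: str


@dataclass(frozen=True)
class Alignment:
    """An optimal move sequence with its total cost."""

    moves: tuple[Move, ...]
    cost: float

    def projection(self, kinds: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(m.activity for m in self.moves if m.kind in kinds)


@dataclass(frozen=True)
class ConformanceMetrics:
    fitness: float
    precision: float
    backwards_precision: float
    balanced_precision: float
    f1: float
    generalization: float
    simplicity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass(frozen=True)
class DeviationRecord:
    """A typed, root-caused structural deviation of one case.

    ``segment`` indexes the trace events involved (for rework loops the
    repeated, removable events); ``delay_hours`` is the attributed waiting
    delay and ``span_hours`` the internal span of the involved events.
    """

    case_id: str
    type: str  # skipped_step | resequenced | loop_rework | extra_activity
    activities: tuple[str, ...]
    delay_hours: float = 0.0
    root_cause: str = "human"
    segment: tuple[int, int] | None = None
    span_hours: float = 0.0


@dataclass(frozen=True)
class DeviationSummary:
    deviant_case_pct: float
    loop_case_pct: float
    mean_loop_delay_hours: float
    counts_per_type: Mapping[str, int] = field(default_factory=dict)


#: (type, activity) -> root-cause category; '*' is the per-type fallback.
DEFAULT_ROOT_CAUSE_RULES: dict[tuple[str, str], str] = {
    ("skipped_step", "Record Handling"): "human",
    ("skipped_step", "Nurse and Medication Basket"): "human",
    ("skipped_step", "Chemotherapy"): "technical",
    ("skipped_step", "Injection"): "technical",
    ("skipped_step", "Billing"): "organizational",
    ("skipped_step", "*"): "human",
    ("resequenced", "*"): "organizational",
    ("loop_rework", "*"): "human",
    ("extra_activity", "*"): "technical",
}


# ---------------------------------------------------------------------------
# Optimal alignment
# ---------------------------------------------------------------------------


def align_trace(
    trace: Trace | Sequence[str],
    model: NormativeModel,
    costs: Mapping[str, float] | None = None,
) -> Alignment:
    """Optimal alignment of a trace against the sequential model.

    Ties are broken by preferring synchronous moves, then model moves as
    early as possible.  Activities outside the model vocabulary are legal and
    become log-only moves; the empty trace aligns as all model-only moves.
    """
    seq = trace.activities if isinstance(trace, Trace) else tuple(trace)
    mseq = tuple(model.activities)
    c = dict(DEFAULT_COSTS, **(costs or {}))
    m, n = len(seq), len(mseq)
    # suffix costs S[i][j]: optimal cost aligning seq[i:] vs mseq[j:]
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    for j in range(n - 1, -1, -1):
        S[m][j] = S[m][j + 1] + c[MODEL_ONLY]
    for i in range(m - 1, -1, -1):
        S[i][n] = S[i + 1][n] + c[LOG_ONLY]
        for j in range(n - 1, -1, -1):
            best = min(S[i][j + 1] + c[MODEL_ONLY], S[i + 1][j] + c[LOG_ONLY])
            if seq[i] == mseq[j]:
                best = min(best, S[i + 1][j + 1] + c[SYNC])
            S[i][j] = best
    moves: list[Move] = []
    i = j = 0
    while i < m or j < n:
        if i < m and j < n and seq[i] == mseq[j] and math.isclose(S[i][j], S[i + 1][j + 1] + c[SYNC]):
            moves.append(Move(SYNC, seq[i]))
            i += 1
            j += 1
        elif j < n and math.isclose(S[i][j], S[i][j + 1] + c[MODEL_ONLY]):
            moves.append(Move(MODEL_ONLY, mseq[j]))
            j += 1
        else:
            moves.append(Move(LOG_ONLY, seq[i]))
            i += 1
    return Alignment(tuple(moves), S[0][0])


def align_log(log: EventLog, model: NormativeModel, costs=None) -> dict[str, Alignment]:
    return {t.case_id: align_trace(t, model, costs) for t in log.traces}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def trace_fitness(alignment: Alignment, trace: Trace | Sequence[str], model: NormativeModel) -> float:
    """Replay fitness 1 - cost / (|trace| + |model|); 1 exactly when cost 0."""
    length = len(trace.activities) if isinstance(trace, Trace) else len(trace)
    denom = length + len(model)
    if denom == 0:
        return 1.0
    return 1.0 - alignment.cost / denom


def log_fitness(log: EventLog, model: NormativeModel, weighted: bool = False) -> float:
    """Unweighted mean of per-trace fitness (cost-weighted variant optional)."""
    if len(log) == 0:
        raise ValueError("fitness is undefined for an empty log")
    if not weighted:
        return sum(
            trace_fitness(align_trace(t, model), t, model) for t in log.traces
        ) / len(log)
    total_cost = 0.0
    total_denom = 0
    for t in log.traces:
        total_cost += align_trace(t, model).cost
        total_denom += len(t) + len(model)
    return 1.0 - total_cost / total_denom


def _escaping_edges_precision(log: EventLog, model: NormativeModel) -> float:
    """Escaping-edges precision over the prefix automaton of aligned model runs.

    Every alignment's model run traverses the full chain, so each visited
    non-final state records the model transition actually taken; precision at
    a state is observed-outgoing over model-allowed-outgoing, visit-weighted.
    A strictly sequential model allows exactly one transition per state, so
    any non-empty log yields 1.0; the formula is kept general for clarity.
    """
    if len(log) == 0:
        raise ValueError("precision is undefined for an empty log")
    n_states = len(model)  # non-final states 0..n-1
    visits = [0] * n_states
    observed: list[set[str]] = [set() for _ in range(n_states)]
    for t in log.traces:
        alignment = align_trace(t, model)
        state = 0
        for move in alignment.moves:
            if move.kind in (SYNC, MODEL_ONLY):
                visits[state] += 1
                observed[state].add(move.activity)
                state += 1
    num = 0.0
    den = 0
    for s in range(n_states):
        if visits[s] == 0:
            continue
        allowed = 1  # chain: exactly one enabled transition per non-final state
        num += visits[s] * min(len(observed[s]), allowed) / allowed
        den += visits[s]
    return num / den if den else 1.0


def log_precision(log: EventLog, model: NormativeModel) -> float:
    """Escaping-edges precision of the model w.r.t. the aligned log."""
    return _escaping_edges_precision(log, model)


def backwards_precision(log: EventLog, model: NormativeModel) -> float:
    """Precision of the reversed traces against the reversed model.

    Timestamps are irrelevant to precision, so only the activity order is
    reversed (each event keeps a placeholder timestamp).
    """
    rev_log = EventLog(
        tuple(
            Trace(
                t.case_id,
                tuple(
                    replace(ev, timestamp=t.events[0].timestamp)
                    for ev in reversed(t.events)
                ),
                t.meta,
            )
            for t in log.traces
        ),
        log.meta,
    )
    return _escaping_edges_precision(rev_log, model.reversed())


def combined_metrics(
    fitness: float,
    precision: float,
    backwards: float,
    generalization: float = 0.0,
    simplicity: float = 0.0,
) -> ConformanceMetrics:
    """Derive F1 (harmonic mean of fitness and precision) and balanced precision.

    Balanced precision is the arithmetic mean of precision and backwards
    precision (the average that reproduces the published value).
    """
    for name, v in (("fitness", fitness), ("precision", precision), ("backwards", backwards)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    f1 = 0.0 if fitness + precision == 0 else 2 * fitness * precision / (fitness + precision)
    balanced = (precision + backwards) / 2.0
    return ConformanceMetrics(fitness, precision, backwards, balanced, f1, generalization, simplicity)


def structural_metrics(model: NormativeModel, log: EventLog) -> tuple[float, float]:
    """Event-class generalization and degree-based simplicity, both in [0, 1].

    Generalization is 1 - mean(1/sqrt(executions)) over model transitions
    (0 by convention when the model was never replayed).  Simplicity scores
    the place-transition chain by node-degree regularity,
    1 / (1 + |mean degree - 2|), with 1 by convention for a single-transition
    model.  Both are informational; neither is a calibration target.
    """
    n_exec = len(log)  # every aligned model run fires every chain transition
    if n_exec == 0:
        generalization = 0.0
    else:
        generalization = 1.0 - sum(1.0 / math.sqrt(n_exec) for _ in model.activities) / len(model)
    L = len(model)
    if L <= 1:
        simplicity = 1.0
    else:
        n_nodes = 2 * L + 1
        n_arcs = 2 * L
        mean_degree = 2.0 * n_arcs / n_nodes
        simplicity = 1.0 / (1.0 + abs(mean_degree - 2.0))
    return generalization, simplicity


# ---------------------------------------------------------------------------
# Deviation classification
# ---------------------------------------------------------------------------


def _loop_segments(trace: Trace) -> list[tuple[int, int]]:
    """Maximal runs of events whose activity already occurred earlier."""
    seen: set[str] = set()
    segments: list[tuple[int, int]] = []
    i = 0
    acts = trace.activities
    while i < len(acts):
        if acts[i] in seen:
            j = i
            while j + 1 < len(acts) and acts[j + 1] in seen:
                j += 1
            segments.append((i, j + 1))
            i = j + 1
        else:
            seen.add(acts[i])
            i += 1
    return segments


def _root_cause(rules: Mapping[tuple[str, str], str], dev_type: str, activities: Sequence[str]) -> str:
    for a in activities:
        if (dev_type, a) in rules:
            return rules[(dev_type, a)]
    return rules.get((dev_type, "*"), "human")


def classify_deviations(
    alignments: Mapping[str, Alignment],
    log: EventLog,
    model: NormativeModel,
    rules: Mapping[tuple[str, str], str] | None = None,
    ignore_trailing_model_moves: bool = True,
) -> list[DeviationRecord]:
    """Classify per-case deviations in priority order.

    1. any activity occurring twice or more -> ``loop_rework`` (one record per
       maximal repeated segment; attributed delay = waiting gap before the
       segment, span = internal segment span);
    2. an unmatched log move and model move on the same single-occurrence
       activity -> ``resequenced``;
    3./4. remaining model-only moves -> ``skipped_step`` (approval-class
       activities first in the emitted order);
    5. remaining log-only moves -> ``extra_activity`` with the occupied
       inter-event gap (capped at 3x the case mean gap) as attributed delay.

    Model-only runs after the last synchronous move are treated as case
    truncation (an incomplete journey, not a skipped step) when
    ``ignore_trailing_model_moves`` is set.
    """
    rules = dict(DEFAULT_ROOT_CAUSE_RULES, **(rules or {}))
    records: list[DeviationRecord] = []
    for trace in log.traces:
        alignment = alignments[trace.case_id]
        acts = trace.activities
        # --- rule 1: rework loops on the raw trace
        repeat_positions: set[int] = set()
        for a, b in _loop_segments(trace):
            repeat_positions.update(range(a, b))
            t_pred = trace.events[a - 1].timestamp  # a >= 1: a repeat cannot open a trace
            t_first = trace.events[a].timestamp
            t_last = trace.events[b - 1].timestamp
            records.append(
                DeviationRecord(
                    case_id=trace.case_id,
                    type="loop_rework",
                    activities=tuple(sorted(set(acts[a:b]))),
                    delay_hours=(t_first - t_pred).total_seconds() / 3600.0,
                    root_cause=_root_cause(rules, "loop_rework", sorted(set(acts[a:b]))),
                    segment=(a, b),
                    span_hours=(t_last - t_first).total_seconds() / 3600.0,
                )
            )
        # --- walk moves, mapping log moves to trace positions
        log_only: list[tuple[int, str]] = []
        model_only: list[tuple[int, str]] = []
        pos = 0
        last_sync_moveidx = -1
        for k, move in enumerate(alignment.moves):
            if move.kind == SYNC:
                last_sync_moveidx = k
                pos += 1
            elif move.kind == LOG_ONLY:
                if pos not in repeat_positions:
                    log_only.append((pos, move.activity))
                pos += 1
        mstate = 0
        for k, move in enumerate(alignment.moves):
            if move.kind in (SYNC, MODEL_ONLY):
                if move.kind == MODEL_ONLY:
                    if not (ignore_trailing_model_moves and k > last_sync_moveidx):
                        model_only.append((mstate, move.activity))
                mstate += 1
        # --- rule 2: crossed same-activity pairs -> resequenced
        used_model: set[int] = set()
        used_log: set[int] = set()
        for li, (lp, la) in enumerate(log_only):
            for mi, (mp, ma) in enumerate(model_only):
                if mi in used_model or ma != la:
                    continue
                used_log.add(li)
                used_model.add(mi)
                records.append(
                    DeviationRecord(
                        case_id=trace.case_id,
                        type="resequenced",
                        activities=(la,),
                        root_cause=_root_cause(rules, "resequenced", [la]),
                        segment=(lp, lp + 1),
                    )
                )
                break
        # --- rules 3/4: remaining model-only -> skipped_step (approval first)
        remaining_model = [mo for i, mo in enumerate(model_only) if i not in used_model]
        remaining_model.sort(key=lambda t: (t[1] not in model.approval_class, t[0]))
        for mp, ma in remaining_model:
            records.append(
                DeviationRecord(
                    case_id=trace.case_id,
                    type="skipped_step",
                    activities=(ma,),
                    root_cause=_root_cause(rules, "skipped_step", [ma]),
                )
            )
        # --- rule 5: remaining log-only -> extra_activity
        remaining_log = [lo for i, lo in enumerate(log_only) if i not in used_log]
        if remaining_log and len(trace) > 1:
            gaps = [
                (b.timestamp - a.timestamp).total_seconds() / 3600.0
                for a, b in zip(trace.events, trace.events[1:])
            ]
            mean_gap = sum(gaps) / len(gaps)
            for lp, la in remaining_log:
                occupied = gaps[lp - 1] if lp >= 1 else (gaps[0] if gaps else 0.0)
                records.append(
                    DeviationRecord(
                        case_id=trace.case_id,
                        type="extra_activity",
                        activities=(la,),
                        delay_hours=min(occupied, 3.0 * mean_gap),
                        root_cause=_root_cause(rules, "extra_activity", [la]),
                        segment=(lp, lp + 1),
                    )
                )
        elif remaining_log:
            for lp, la in remaining_log:
                records.append(
                    DeviationRecord(
                        case_id=trace.case_id,
                        type="extra_activity",
                        activities=(la,),
                        root_cause=_root_cause(rules, "extra_activity", [la]),
                        segment=(lp, lp + 1),
                    )
                )
    return records


def deviation_summary(records: Sequence[DeviationRecord], log: EventLog) -> DeviationSummary:
    """Case-level shares and loop-delay statistics of a record set."""
    n_cases = len(log)
    if n_cases == 0:
        return DeviationSummary(0.0, 0.0, 0.0, {})
    deviant_cases = {r.case_id for r in records}
    loop_delay_by_case: dict[str, float] = {}
    for r in records:
        if r.type == "loop_rework":
            loop_delay_by_case[r.case_id] = loop_delay_by_case.get(r.case_id, 0.0) + r.delay_hours
    counts: dict[str, int] = {}
    for r in records:
        counts[r.type] = counts.get(r.type, 0) + 1
    mean_loop = (
        sum(loop_delay_by_case.values()) / len(loop_delay_by_case) if loop_delay_by_case else 0.0
    )
    return DeviationSummary(
        deviant_case_pct=100.0 * len(deviant_cases) / n_cases,
        loop_case_pct=100.0 * len(loop_delay_by_case) / n_cases,
        mean_loop_delay_hours=mean_loop,
        counts_per_type=counts,
    )


def records_to_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    """Deviation records as an exportable table."""
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "type": r.type,
                "activities": "|".join(r.activities),
                "delay_hours": round(r.delay_hours, 6),
                "root_cause": r.root_cause,
            }
            for r in records
        ],
        columns=["case_id", "type", "activities", "delay_hours", "root_cause"],
    )
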