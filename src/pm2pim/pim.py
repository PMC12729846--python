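"""Predictive Impact Model: deterministic what-if remodeling of an event log.

A *scenario* specifies which classified deviations are removed or mitigated.
Remodeling is deterministic timestamp surgery on each case: rework loops are
deleted (their internal span vanishes with the events and their attributed
waiting delay is recovered, scaled by the sensitivity knob), resequenced
events are reordered into canonical order within their original span, and
skipped steps are removal-only (no event is ever inserted, so a remodeled
case never gains workload or cycle time).  KPI reductions follow the
standard reduction formula (baseline - scenario) / baseline x 100 computed
on the means of the paired per-case KPIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Mapping, Sequence

import pandas as pd

from .conformance import DeviationRecord
from .event_log import EventLog, Trace
from .kpi import KPIRecord, case_kpis
from .normative_model import NormativeModel, default_model

__all__ = [
    "Scenario",
    "ReductionResult",
    "ScenarioResult",
    "scenario_defaults",
    "reduction_pct",
    "remodel_trace",
    "run_scenario",
    "sensitivity_ofat",
]

ALL_DEVIATION_TYPES = frozenset({"loop_rework", "resequenced", "skipped_step", "extra_activity"})


@dataclass(frozen=True)
class Scenario:
    """A what-if improvement scenario.

    ``class_filters`` optionally restricts a deviation type to records whose
    activities intersect the given label set (e.g. only billing-related
    rework); ``delay_scale`` multiplies every attributed waiting delay and is
    the one-factor-at-a-time sensitivity knob.
    """

    name: str
    mode: str  # current_optimization | full_adherence
    deviation_types_removed: frozenset[str]
    class_filters: Mapping[str, frozenset[str] | None] = field(default_factory=dict)
    delay_scale: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.delay_scale <= 0:
            raise ValueError("delay_scale must be positive")
        if self.mode == "full_adherence" and self.deviation_types_removed != ALL_DEVIATION_TYPES:
            raise ValueError("full_adherence removes all four deviation types")

    def removes(self, record: DeviationRecord) -> bool:
        if record.type not in self.deviation_types_removed:
            return False
        flt = self.class_filters.get(record.type)
        if flt is None:
            return True
        return bool(set(record.activities) & set(flt))


@dataclass(frozen=True)
class ReductionResult:
    baseline_value: float
    scenario_value: float
    reduction_pct: float


@dataclass(frozen=True)
class ScenarioResult:
    """Paired baseline/remodeled per-case KPIs and the mean reductions."""

    scenario: Scenario
    baseline: tuple[KPIRecord, ...]
    remodeled: tuple[KPIRecord, ...]
    cycle: ReductionResult
    workload: ReductionResult
    clamp_warnings: int = 0

    def paired_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": b.case_id,
                    "cycle_baseline_days": b.cycle_time_days,
                    "cycle_scenario_days": s.cycle_time_days,
                    "workload_baseline": b.workload,
                    "workload_scenario": s.workload,
                }
                for b, s in zip(self.baseline, self.remodeled)
            ]
        )


def scenario_defaults() -> tuple[Scenario, Scenario]:
    """The two standard scenarios.

    *Current optimization* mitigates the top-frequency, operationally
    addressable deviation classes: billing-correction rework loops and
    resequenced records.  *Full adherence* enforces the normative sequence by
    removing every classified deviation.
    """
    current = Scenario(
        name="Current Optimization",
        mode="current_optimization",
        deviation_types_removed=frozenset({"loop_rework", "resequenced"}),
        class_filters={"loop_rework": frozenset({"Billing"})},
        description="remove billing-correction rework and resequencing",
    )
    full = Scenario(
        name="Full Adherence",
        mode="full_adherence",
        deviation_types_removed=ALL_DEVIATION_TYPES,
        description="enforce the normative sequence for all cases",
    )
    return current, full


def reduction_pct(baseline_value: float, scenario_value: float) -> float:
    """(BV - SV) / BV x 100; positive means improvement."""
    if baseline_value <= 0:
        raise ValueError(f"baseline value must be positive, got {baseline_value}")
    return (baseline_value - scenario_value) / baseline_value * 100.0


def remodel_trace(
    trace: Trace,
    deviations: Sequence[DeviationRecord],
    scenario: Scenario,
    model: NormativeModel | None = None,
) -> tuple[Trace, int]:
    """Apply the scenario's structural changes to one case.

    Returns the remodeled trace and the number of clamped (would-be negative)
    inter-event gaps.  Deterministic; a canonical trace is returned unchanged.
    """
    model = model or default_model()
    removed = [r for r in deviations if scenario.removes(r)]
    if not removed:
        return trace, 0

    events = list(trace.events)
    clamps = 0

    # --- delete rework segments / extra events, recovering attributed delay
    deletions: list[tuple[int, int, float]] = []  # (start, stop, shift_days)
    for rec in removed:
        if rec.type == "loop_rework" and rec.segment is not None:
            span_days = rec.span_hours / 24.0
            shift = span_days + (rec.delay_hours / 24.0) * scenario.delay_scale
            deletions.append((rec.segment[0], rec.segment[1], shift))
        elif rec.type == "extra_activity" and rec.segment is not None:
            shift = (rec.delay_hours / 24.0) * scenario.delay_scale
            deletions.append((rec.segment[0], rec.segment[1], shift))
    if deletions:
        deletions.sort()
        keep: list = []
        shift_days = 0.0
        di = 0
        last_kept_ts = None
        for i, ev in enumerate(events):
            if di < len(deletions) and deletions[di][0] <= i < deletions[di][1]:
                if i == deletions[di][1] - 1:
                    shift_days += deletions[di][2]
                    di += 1
                continue
            ts = ev.timestamp - timedelta(seconds=round(shift_days * 86400.0))
            if last_kept_ts is not None and ts <= last_kept_ts:
                clamps += 1
                ts = last_kept_ts + timedelta(seconds=60)
            keep.append(replace(ev, timestamp=ts))
            last_kept_ts = ts
        events = keep

    # --- reorder resequenced events into canonical order within their span
    if any(r.type == "resequenced" for r in removed):
        order = {a: i for i, a in enumerate(model.activities)}
        slots = [ev.timestamp for ev in events]
        sorted_events = sorted(
            events, key=lambda ev: (order.get(ev.activity, len(order)),)
        )
        events = [replace(ev, timestamp=ts) for ev, ts in zip(sorted_events, slots)]

    # skipped_step: removal-only semantics, nothing to insert
    if not events:
        return trace, clamps
    return Trace(trace.case_id, tuple(events), trace.meta), clamps


def run_scenario(
    log: EventLog,
    deviations: Mapping[str, Sequence[DeviationRecord]] | Sequence[DeviationRecord],
    scenario: Scenario,
    model: NormativeModel | None = None,
) -> ScenarioResult:
    """Remodel every case and compute the paired KPI reductions on the means."""
    if len(log) == 0:
        raise ValueError("cannot run a scenario on an empty log")
    if not isinstance(deviations, Mapping):
        by_case: dict[str, list[DeviationRecord]] = {}
        for r in deviations:
            by_case.setdefault(r.case_id, []).append(r)
        deviations = by_case
    baseline: list[KPIRecord] = []
    remodeled: list[KPIRecord] = []
    clamps = 0
    for trace in log.traces:
        baseline.append(case_kpis(trace))
        new_trace, c = remodel_trace(trace, deviations.get(trace.case_id, ()), scenario, model)
        clamps += c
        remodeled.append(case_kpis(new_trace))
    n = len(baseline)
    bc = sum(r.cycle_time_days for r in baseline) / n
    sc = sum(r.cycle_time_days for r in remodeled) / n
    bw = sum(r.workload for r in baseline) / n
    sw = sum(r.workload for r in remodeled) / n
    return ScenarioResult(
        scenario=scenario,
        baseline=tuple(baseline),
        remodeled=tuple(remodeled),
        cycle=ReductionResult(bc, sc, reduction_pct(bc, sc)),
        workload=ReductionResult(bw, sw, reduction_pct(bw, sw)),
        clamp_warnings=clamps,
    )


def sensitivity_ofat(
    log: EventLog,
    deviations,
    scenario: Scenario,
    scales: Sequence[float] = (0.9, 1.0, 1.1),
    model: NormativeModel | None = None,
) -> pd.DataFrame:
    """One-factor-at-a-time sensitivity over the delay-attribution scale.

    Only ``delay_scale`` is varied; event-removal decisions are not, so
    workload reductions are delay-invariant by construction.  The scale-1.0
    row reproduces the unperturbed run exactly.
    """
    if any(s <= 0 for s in scales):
        raise ValueError("delay scales must be positive")
    rows = []
    for s in scales:
        label = (
            "Baseline"
            if s == 1.0
            else f"Delay {'+' if s > 1 else '-'}{abs(s - 1.0) * 100:.0f}%"
        )
        result = run_scenario(log, deviations, replace(scenario, delay_scale=s), model)
        rows.append(
            {
                "scenario": scenario.name,
                "parameter_change": label,
                "delay_scale": s,
                "cycle_reduction_pct": result.cycle.reduction_pct,
                "workload_reduction_pct": result.workload.reduction_pct,
            }
        )
    return pd.DataFrame(rows)
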