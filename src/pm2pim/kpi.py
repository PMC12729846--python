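"""Case-level performance indicators and descriptive tables.

Two KPIs drive the whole pipeline: *cycle time* (last minus first timestamp
of a case, in days of exactly 86,400 s) and *workload* (number of activities
in the case).  The descriptive products are the activity frequency table,
the process-variant table and the path-length distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .event_log import EventLog, Trace

__all__ = [
    "KPIRecord",
    "KPISummary",
    "PathLengthStats",
    "case_kpis",
    "kpi_summary",
    "kpi_frame",
    "activity_frequency_table",
    "variant_table",
    "path_length_stats",
]

_DAY_SECONDS = 86400.0


@dataclass(frozen=True)
class KPIRecord:
    case_id: str
    cycle_time_days: float
    workload: int


@dataclass(frozen=True)
class KPISummary:
    n: int
    cycle_mean: float
    cycle_sd: float
    workload_mean: float
    workload_sd: float


@dataclass(frozen=True)
class PathLengthStats:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    outlier_case_ids: tuple[str, ...]


def case_kpis(trace: Trace) -> KPIRecord:
    """Cycle time (days) and workload (activity count) of one case."""
    if len(trace) == 0:
        raise ValueError("cannot compute KPIs of an empty trace")
    cycle = (trace.end - trace.start).total_seconds() / _DAY_SECONDS
    return KPIRecord(trace.case_id, cycle, len(trace))


def kpi_frame(log: EventLog) -> pd.DataFrame:
    """Per-case KPI table (case_id, cycle_time_days, workload)."""
    recs = [case_kpis(t) for t in log.traces]
    return pd.DataFrame(
        [{"case_id": r.case_id, "cycle_time_days": r.cycle_time_days, "workload": r.workload} for r in recs]
    )


def kpi_summary(log: EventLog) -> KPISummary:
    """Sample mean and sd (n-1 denominator) of both KPIs across cases."""
    if len(log) == 0:
        raise ValueError("KPI summary is undefined for an empty log")
    recs = [case_kpis(t) for t in log.traces]
    cycles = np.array([r.cycle_time_days for r in recs])
    loads = np.array([r.workload for r in recs], dtype=float)
    if len(recs) == 1:
        warnings.warn("sample sd undefined for n=1; reporting 0", stacklevel=2)
        return KPISummary(1, float(cycles[0]), 0.0, float(loads[0]), 0.0)
    return KPISummary(
        len(recs),
        float(cycles.mean()),
        float(cycles.std(ddof=1)),
        float(loads.mean()),
        float(loads.std(ddof=1)),
    )


def _pct_3dp(count: int, total: int) -> float:
    """Percentage rounded half-up to 3 decimals (printed-table convention)."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * Decimal(100) / Decimal(total)
    return float(pct.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def activity_frequency_table(log: EventLog) -> pd.DataFrame:
    """Activity counts ranked by frequency with half-up 3-decimal percentages."""
    counts: dict[str, int] = {}
    for trace in log.traces:
        for ev in trace.events:
            counts[ev.activity] = counts.get(ev.activity, 0) + 1
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {"rank": i, "activity": a, "count": c, "pct": _pct_3dp(c, total)}
            for i, (a, c) in enumerate(rows, start=1)
        ],
        columns=["rank", "activity", "count", "pct"],
    )


def variant_table(log: EventLog) -> pd.DataFrame:
    """One row per distinct activity sequence, sorted by count then sequence."""
    counts: dict[tuple[str, ...], int] = {}
    for trace in log.traces:
        counts[trace.activities] = counts.get(trace.activities, 0) + 1
    n = len(log)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {"sequence": " > ".join(seq), "count": c, "share": c / n if n else 0.0}
            for seq, c in rows
        ],
        columns=["sequence", "count", "share"],
    )


def path_length_stats(log: EventLog) -> PathLengthStats:
    """Path-length five-number summary with 1.5 x IQR whisker outliers.

    Quartiles use inclusive linear interpolation (numpy's default).
    """
    if len(log) == 0:
        raise ValueError("path-length statistics undefined for an empty log")
    lens = np.array([len(t) for t in log.traces], dtype=float)
    q1, med, q3 = np.percentile(lens, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(t.case_id for t in log.traces if not (lo <= len(t) <= hi))
    return PathLengthStats(
        float(lens.min()), float(q1), float(med), float(q3), float(lens.max()), float(lens.mean()), outliers
    )
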