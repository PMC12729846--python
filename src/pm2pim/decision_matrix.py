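"""Root-cause aggregation and the frequency x impact prioritization matrix.

Each deviation category is scored by multiplying its relative frequency
(percent of cases) with its average cycle-time impact (percent inflation);
the composite score maps to priority bands:  High (>= 40), Medium-High
([25, 40)), Medium ([10, 25)) and Low ([0, 10)).  Bands are half-open real
intervals so adjacent bands leave no gaps.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .conformance import DeviationRecord

__all__ = [
    "DEFAULT_MATRIX_INPUTS",
    "impact_frequency_score",
    "priority_band",
    "build_decision_matrix",
    "root_cause_summary",
]

#: Default deviation categories: label -> (frequency %, impact %, root cause, mitigation).
DEFAULT_MATRIX_INPUTS: dict[str, tuple[float, float, str, str]] = {
    "Skipped Approval Step": (18.0, 2.4, "human", "Staff refresher training; automated approval alerts"),
    "Resequenced Treatment Record": (14.0, 2.1, "technical", "HIS-pharmacy system integration patch"),
    "Incomplete Prescription Data": (9.0, 1.9, "human", "Mandatory data validation at entry"),
    "Queue Delay (Pharmacy)": (7.0, 1.6, "organizational", "Shift synchronization; resource balancing"),
    "Barcode Scan Error": (6.0, 1.4, "technical", "Scanner/API real-time I/O monitoring"),
    "Missed Double-Check": (5.0, 1.2, "human", "Standardized double-check automated prompt"),
}

_BANDS: tuple[tuple[float, str], ...] = (
    (40.0, "High"),
    (25.0, "Medium-High"),
    (10.0, "Medium"),
    (0.0, "Low"),
)


def impact_frequency_score(frequency_pct: float, impact_pct: float) -> float:
    """Composite score: frequency times impact (both in percent)."""
    if frequency_pct < 0 or impact_pct < 0:
        raise ValueError("frequency and impact must be non-negative")
    return frequency_pct * impact_pct


def priority_band(score: float) -> str:
    """Map a composite score to its priority band (half-open intervals)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    for lower, label in _BANDS:
        if score >= lower:
            return label
    return "Low"


def build_decision_matrix(
    frequencies: Mapping[str, float] | None = None,
    impact_estimates: Mapping[str, float] | None = None,
    cause_map: Mapping[str, str] | None = None,
    mitigations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Score and band deviation categories, sorted by score descending.

    With no arguments the published six-category defaults are used.  When
    ``frequencies`` is given, every label must also appear in
    ``impact_estimates`` and ``cause_map``.  Equal scores tie-break
    alphabetically; the output ordering is invariant to input ordering.
    """
    if frequencies is None:
        frequencies = {k: v[0] for k, v in DEFAULT_MATRIX_INPUTS.items()}
        impact_estimates = dict(
            {k: v[1] for k, v in DEFAULT_MATRIX_INPUTS.items()}, **(impact_estimates or {})
        )
        cause_map = dict(
            {k: v[2] for k, v in DEFAULT_MATRIX_INPUTS.items()}, **(cause_map or {})
        )
        mitigations = dict(
            {k: v[3] for k, v in DEFAULT_MATRIX_INPUTS.items()}, **(mitigations or {})
        )
    impact_estimates = impact_estimates or {}
    cause_map = cause_map or {}
    mitigations = mitigations or {}
    rows = []
    for label in frequencies:
        if label not in impact_estimates:
            raise KeyError(f"no impact estimate for deviation label {label!r}")
        if label not in cause_map:
            raise KeyError(f"no root cause for deviation label {label!r}")
        score = impact_frequency_score(frequencies[label], impact_estimates[label])
        rows.append(
            {
                "deviation_label": label,
                "root_cause": cause_map[label],
                "frequency_pct": frequencies[label],
                "impact_pct": impact_estimates[label],
                "score": round(score, 10),
                "priority": priority_band(score),
                "mitigation": mitigations.get(label, ""),
            }
        )
    rows.sort(key=lambda r: (-r["score"], r["deviation_label"]))
    return pd.DataFrame(
        rows,
        columns=[
            "deviation_label",
            "root_cause",
            "frequency_pct",
            "impact_pct",
            "score",
            "priority",
            "mitigation",
        ],
    )


def root_cause_summary(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    """Relative frequency and mean attributed delay per root-cause category."""
    if not records:
        return pd.DataFrame(columns=["root_cause", "n_records", "frequency_pct", "mean_delay_hours"])
    by_cause: dict[str, list[DeviationRecord]] = {}
    for r in records:
        by_cause.setdefault(r.root_cause, []).append(r)
    total = len(records)
    rows = [
        {
            "root_cause": cause,
            "n_records": len(rs),
            "frequency_pct": 100.0 * len(rs) / total,
            "mean_delay_hours": sum(r.delay_hours for r in rs) / len(rs),
        }
        for cause, rs in sorted(by_cause.items(), key=lambda kv: -len(kv[1]))
    ]
    return pd.DataFrame(rows)
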