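"""Pipeline orchestration, configuration and figure-data exports.

Figures are emitted as plain data products (CSV/JSON) so downstream
rendering — and testing — operates on numbers, not pixels: Sankey-style
flow edges with per-case shares and deviation color classes, a deviation
map annotating the sequential net, and grouped scenario bars.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .conformance import (
    DeviationRecord,
    align_log,
    backwards_precision,
    classify_deviations,
    combined_metrics,
    deviation_summary,
    log_fitness,
    log_precision,
    records_to_frame,
    structural_metrics,
)
from .decision_matrix import build_decision_matrix, root_cause_summary
from .event_log import EventLog, read_csv, read_xes, write_xes
from .kpi import activity_frequency_table, kpi_frame, kpi_summary, path_length_stats, variant_table
from .normative_model import NormativeModel, default_model, full_adherence_filter, to_pnml
from .pim import Scenario, run_scenario, scenario_defaults, sensitivity_ofat
from .stats import StatsConfig, friedman, paired_t, shapiro_wilk, statistics_report, wilcoxon_signed_rank
from .synthetic_log import DEFAULT_SEED, GeneratorConfig, calibration_report, generate_log

__all__ = ["RunConfig", "sankey_flows", "deviation_map", "scenario_bars", "run_pipeline"]

logger = logging.getLogger("pm2pim")


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration (YAML/JSON file or keyword construction)."""

    log_path: str | None = None
    log_format: str = "xes"  # xes | csv
    column_map: Mapping[str, str] = field(default_factory=dict)
    generator: Mapping[str, object] | None = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    out_dir: str = "pm2pim_out"
    alpha: float = 0.05
    sensitivity_scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if "sensitivity_scales" in known:
            known["sensitivity_scales"] = tuple(known["sensitivity_scales"])
        return cls(**known)

    def generator_config(self) -> GeneratorConfig:
        params = dict(self.generator or {})
        params.setdefault("seed", self.seed)
        if "events_per_case_bounds" in params:
            params["events_per_case_bounds"] = tuple(params["events_per_case_bounds"])
        return GeneratorConfig(**params)


def sankey_flows(
    log: EventLog, model: NormativeModel, records: Sequence[DeviationRecord]
) -> dict:
    """Directly-follows flow edges with per-case shares and color classes.

    Normative edges are consecutive pairs of the canonical chain; other edges
    are colored by the deviation class they evidence: backward jumps into
    already-visited territory are loops, backward jumps otherwise
    resequencing, and forward jumps over unvisited steps are skips.
    """
    order = {a: i for i, a in enumerate(model.activities)}
    edge_cases: dict[tuple[str, str], set[str]] = {}
    for trace in log.traces:
        for a, b in zip(trace.events, trace.events[1:]):
            edge_cases.setdefault((a.activity, b.activity), set()).add(trace.case_id)
    loop_cases = {r.case_id for r in records if r.type == "loop_rework"}
    reseq_cases = {r.case_id for r in records if r.type == "resequenced"}
    n = max(len(log), 1)
    edges = []
    for (src, dst), cases in sorted(edge_cases.items()):
        i, j = order.get(src), order.get(dst)
        if i is not None and j is not None and j == i + 1:
            color = "normative"
        elif i is not None and j is not None and j <= i:
            color = "loop" if cases & loop_cases else "resequenced"
        else:
            color = "skipped"
        edges.append(
            {
                "source": src,
                "target": dst,
                "n_cases": len(cases),
                "case_share": len(cases) / n,
                "color_class": color,
            }
        )
    return {"node_order": list(model.activities), "edges": edges}


def deviation_map(model: NormativeModel, records: Sequence[DeviationRecord]) -> dict:
    """Per-activity deviation counts by class, for annotating the chain net."""
    nodes = {a: {"skipped_step": 0, "resequenced": 0, "loop_rework": 0, "extra_activity": 0} for a in model.activities}
    for r in records:
        for a in r.activities:
            if a in nodes:
                nodes[a][r.type] += 1
    return {
        "activities": list(model.activities),
        "markers": nodes,
        "total_records": len(records),
    }


def scenario_bars(results: Sequence) -> pd.DataFrame:
    """Grouped-bar data: baseline at zero, scenarios at their reductions."""
    rows = [{"scenario": "Baseline", "cycle_reduction_pct": 0.0, "workload_reduction_pct": 0.0}]
    for res in results:
        rows.append(
            {
                "scenario": res.scenario.name,
                "cycle_reduction_pct": res.cycle.reduction_pct,
                "workload_reduction_pct": res.workload.reduction_pct,
            }
        )
    return pd.DataFrame(rows)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the output directory.

    Stages: ingest or generate -> conformance -> KPI -> scenarios ->
    sensitivity -> statistics -> decision matrix -> figure data.  The run log
    records seed, configuration hash and package version; a fixed seed makes
    the whole output byte-identical across runs.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configuration"
    try:
        if config.log_path:
            stage = "ingest"
            if config.log_format == "csv":
                log = read_csv(config.log_path, dict(config.column_map) or None)
            else:
                log = read_xes(config.log_path)
        elif config.generator is not None:
            stage = "generate"
            gen_cfg = config.generator_config()
            log = generate_log(gen_cfg, config.seed)
            _write_csv(calibration_report(log, gen_cfg), out / "calibration_report.csv")
            write_xes(log, out / "synthetic_log.xes")
        else:
            raise ValueError("config needs either log_path or a generator block")

        model = default_model()
        to_pnml(model, out / "normative_model.pnml")

        stage = "conformance"
        alignments = align_log(log, model)
        fitness = log_fitness(log, model)
        precision = log_precision(log, model)
        backwards = backwards_precision(log, model)
        gen_m, simp = structural_metrics(model, log)
        metrics = combined_metrics(fitness, precision, backwards, gen_m, simp)
        _write_csv(metrics.to_frame(), out / "metrics.csv")
        records = classify_deviations(alignments, log, model)
        _write_csv(records_to_frame(records), out / "deviations.csv")
        summary = deviation_summary(records, log)

        stage = "kpi"
        _write_csv(activity_frequency_table(log), out / "activity_frequency.csv")
        _write_csv(variant_table(log), out / "variants.csv")
        ks = kpi_summary(log)
        _, n_adherent = full_adherence_filter(log, model)

        stage = "scenarios"
        current, full = scenario_defaults()
        res_current = run_scenario(log, records, current, model)
        res_full = run_scenario(log, records, full, model)
        paired = res_current.paired_frame().merge(
            res_full.paired_frame(), on="case_id", suffixes=("_current", "_full")
        )
        _write_csv(paired, out / "kpi_results.csv")
        means = pd.DataFrame(
            [
                {
                    "kpi": "cycle_time_days",
                    "baseline": res_full.cycle.baseline_value,
                    "current_optimization": res_current.cycle.scenario_value,
                    "full_adherence": res_full.cycle.scenario_value,
                    "current_reduction_pct": res_current.cycle.reduction_pct,
                    "full_reduction_pct": res_full.cycle.reduction_pct,
                },
                {
                    "kpi": "workload",
                    "baseline": res_full.workload.baseline_value,
                    "current_optimization": res_current.workload.scenario_value,
                    "full_adherence": res_full.workload.scenario_value,
                    "current_reduction_pct": res_current.workload.reduction_pct,
                    "full_reduction_pct": res_full.workload.reduction_pct,
                },
            ]
        )
        _write_csv(means, out / "kpi_means.csv")

        stage = "sensitivity"
        sens = pd.concat(
            [
                sensitivity_ofat(log, records, current, config.sensitivity_scales, model),
                sensitivity_ofat(log, records, full, config.sensitivity_scales, model),
            ],
            ignore_index=True,
        )
        _write_csv(sens, out / "sensitivity.csv")

        stage = "statistics"
        scfg = StatsConfig(alpha=config.alpha)
        results = []
        columns = {
            "cycle_time_days": ("cycle_baseline_days", "cycle_scenario_days"),
            "workload": ("workload_baseline", "workload_scenario"),
        }
        per_scenario = {"Current Optimization": res_current, "Full Adherence": res_full}
        for kpi_name, (bcol, scol) in columns.items():
            for scen_name, res in per_scenario.items():
                frame = res.paired_frame()
                tres = paired_t(frame[bcol], frame[scol], scfg)
                results.append(
                    {
                        "test": "paired_t",
                        "kpi": kpi_name,
                        "comparison": f"Baseline vs {scen_name}",
                        "statistic": tres.t,
                        "p": tres.p_two_sided,
                        "effect_size": tres.cohens_d,
                    }
                )
            base = per_scenario["Full Adherence"].paired_frame()[bcol].to_numpy()
            cur = per_scenario["Current Optimization"].paired_frame()[scol].to_numpy()
            ful = per_scenario["Full Adherence"].paired_frame()[scol].to_numpy()
            for name, (a, b) in {
                "Baseline vs Current": (base, cur),
                "Baseline vs Full": (base, ful),
                "Current vs Full": (cur, ful),
            }.items():
                w, p = wilcoxon_signed_rank(a, b)
                results.append(
                    {"test": "wilcoxon", "kpi": kpi_name, "comparison": name, "statistic": w, "p": p}
                )
            chi, p = friedman(pd.DataFrame({"b": base, "c": cur, "f": ful}).to_numpy())
            results.append(
                {
                    "test": "friedman",
                    "kpi": kpi_name,
                    "comparison": "Baseline vs Current vs Full",
                    "statistic": chi,
                    "p": p,
                }
            )
        _write_csv(statistics_report(results, scfg), out / "kpi_statistics.csv")

        stage = "decision_matrix"
        _write_csv(build_decision_matrix(), out / "decision_matrix.csv")
        _write_csv(root_cause_summary(records), out / "root_causes.csv")

        stage = "figures"
        (out / "sankey_flows.json").write_text(
            json.dumps(sankey_flows(log, model, records), indent=1, sort_keys=True), encoding="utf-8"
        )
        (out / "deviation_map.json").write_text(
            json.dumps(deviation_map(model, records), indent=1, sort_keys=True), encoding="utf-8"
        )
        _write_csv(scenario_bars([res_current, res_full]), out / "scenario_bars.csv")

        stage = "run_log"
        cfg_hash = hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in config.__dict__.items()}, sort_keys=True
            ).encode()
        ).hexdigest()[:16]
        run_log = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": cfg_hash,
            "n_cases": len(log),
            "n_events": log.n_events,
            "n_full_adherence": n_adherent,
            "fitness": round(fitness, 6),
            "precision": round(precision, 6),
            "cycle_mean_days": round(ks.cycle_mean, 6),
            "deviant_case_pct": round(summary.deviant_case_pct, 3),
            "clamped_gaps": res_current.clamp_warnings + res_full.clamp_warnings,
            "headline": {
                "current_optimization": {
                    "cycle_reduction_pct": round(res_current.cycle.reduction_pct, 2),
                    "workload_reduction_pct": round(res_current.workload.reduction_pct, 2),
                },
                "full_adherence": {
                    "cycle_reduction_pct": round(res_full.cycle.reduction_pct, 2),
                    "workload_reduction_pct": round(res_full.workload.reduction_pct, 2),
                },
            },
        }
        (out / "run_log.json").write_text(
            json.dumps(run_log, indent=1, sort_keys=True), encoding="utf-8"
        )
        logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
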