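"""Alignments, conformance metrics and deviation classification."""

from __future__ import annotations

import itertools
import json
import math
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm2pim.conformance import (
    LOG_ONLY,
    MODEL_ONLY,
    SYNC,
    align_trace,
    backwards_precision,
    classify_deviations,
    combined_metrics,
    deviation_summary,
    log_fitness,
    log_precision,
    structural_metrics,
    trace_fitness,
)
from pm2pim.event_log import Event, EventLog, Trace
from pm2pim.normative_model import CANONICAL_ACTIVITIES, NormativeModel

T0 = datetime(2024, 3, 1, 8, 0)


def make_trace(case_id, labels, hours=None):
    hours = hours if hours is not None else range(len(labels))
    return Trace(
        case_id,
        tuple(Event(case_id, a, T0 + timedelta(hours=float(h))) for a, h in zip(labels, hours)),
    )


def oracle_min_cost(seq, mseq) -> int:
    """Independent optimum: cost = |trace| + |model| - 2 * LCS.

    LCS is found by exhaustive enumeration of all model subsequences,
    keeping the longest that is also a subsequence of the trace.
    """
    def is_subseq(s, t):
        it = iter(t)
        return all(c in it for c in s)

    best = 0
    for r in range(len(mseq), -1, -1):
        for combo in itertools.combinations(mseq, r):
            if is_subseq(combo, seq):
                best = r
                break
        if best == r:
            break
    return len(seq) + len(mseq) - 2 * best


class TestAlignment:
    def test_canonical_trace_cost_zero(self, model):
        a = align_trace(CANONICAL_ACTIVITIES, model)
        assert a.cost == 0 and all(m.kind == SYNC for m in a.moves)

    def test_one_deletion(self, model):
        seq = tuple(a for a in CANONICAL_ACTIVITIES if a != "Injection")
        a = align_trace(seq, model)
        assert a.cost == oracle_min_cost(seq, model.activities) == 1
        assert sum(m.kind == MODEL_ONLY for m in a.moves) == 1

    def test_adjacent_swap_costs_two(self, model):
        seq = list(CANONICAL_ACTIVITIES)
        seq[3], seq[4] = seq[4], seq[3]
        a = align_trace(tuple(seq), model)
        assert a.cost == oracle_min_cost(seq, model.activities) == 2

    def test_out_of_vocabulary_is_log_only(self, model):
        a = align_trace(CANONICAL_ACTIVITIES + ("Imaging",), model)
        assert a.cost == 1
        assert any(m.kind == LOG_ONLY and m.activity == "Imaging" for m in a.moves)

    def test_empty_trace_all_model_moves(self, model):
        a = align_trace((), model)
        assert a.cost == 7 and all(m.kind == MODEL_ONLY for m in a.moves)

    def test_projections_reproduce_trace_and_model(self, model, default_log):
        for t in default_log.traces[::17]:
            a = align_trace(t, model)
            assert a.projection((SYNC, LOG_ONLY)) == t.activities
            assert a.projection((SYNC, MODEL_ONLY)) == tuple(model.activities)

    def test_exhaustive_optimality_small_models(self):
        """DP cost equals the enumeration optimum for every small instance."""
        for L in range(1, 5):
            labels = tuple("ABCD"[:L])
            model = NormativeModel(labels)
            alphabet = labels + ("X",)
            for n in range(0, 5):
                for seq in itertools.product(alphabet, repeat=n):
                    assert align_trace(seq, model).cost == oracle_min_cost(seq, labels)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=4),
        st.lists(st.sampled_from("ABCDX"), min_size=0, max_size=6),
    )
    def test_optimality_property(self, L, seq):
        model = NormativeModel(tuple("ABCD"[:L]))
        assert align_trace(tuple(seq), model).cost == oracle_min_cost(seq, model.activities)


class TestFitness:
    def test_zero_cost_gives_one(self, model):
        a = align_trace(CANONICAL_ACTIVITIES, model)
        assert trace_fitness(a, CANONICAL_ACTIVITIES, model) == 1.0

    def test_empty_trace_bound(self, model):
        a = align_trace((), model)
        assert trace_fitness(a, (), model) == 0.0

    def test_six_event_prefix(self, model):
        seq = CANONICAL_ACTIVITIES[:6]
        a = align_trace(seq, model)
        assert trace_fitness(a, seq, model) == pytest.approx(1 - 1 / 13)

    def test_toy_mean_of_canonical_and_empty(self, model):
        vals = [
            trace_fitness(align_trace(s, model), s, model)
            for s in (CANONICAL_ACTIVITIES, ())
        ]
        assert sum(vals) / 2 == pytest.approx(0.5)

    def test_all_canonical_log(self, model):
        log = EventLog(tuple(make_trace(f"c{i}", CANONICAL_ACTIVITIES) for i in range(3)))
        assert log_fitness(log, model) == 1.0

    def test_empty_log_raises(self, model):
        with pytest.raises(ValueError):
            log_fitness(EventLog(()), model)

    def test_bounds_on_default_log(self, model, default_log):
        f = log_fitness(default_log, model)
        assert 0.0 < f < 1.0


class TestPrecision:
    def test_default_log_precision_one(self, model, default_log):
        assert log_precision(default_log, model) == pytest.approx(1.0)

    def test_single_admission_trace(self, model):
        log = EventLog((make_trace("c", ["Admission"]),))
        p = log_precision(log, model)
        assert 0.0 <= p <= 1.0

    def test_backwards_all_canonical(self, model):
        log = EventLog((make_trace("c", CANONICAL_ACTIVITIES),))
        assert backwards_precision(log, model) == pytest.approx(1.0)

    def test_backwards_on_default_log(self, model, default_log):
        assert abs(backwards_precision(default_log, model) - 0.99) <= 0.01 + 1e-9

    def test_reversal_involution(self, model, default_log):
        """Reversing a reversed computation equals the forward precision."""
        rev_log = EventLog(
            tuple(
                Trace(
                    t.case_id,
                    tuple(
                        Event(t.case_id, ev.activity, T0 + timedelta(hours=i))
                        for i, ev in enumerate(reversed(t.events))
                    ),
                )
                for t in default_log.traces
            )
        )
        assert backwards_precision(rev_log, model.reversed()) == pytest.approx(
            log_precision(default_log, model)
        )


class TestCombinedMetrics:
    def test_published_arithmetic(self):
        m = combined_metrics(0.97, 1.00, 0.99)
        assert round(m.f1, 3) == 0.985
        assert m.balanced_precision == pytest.approx(0.995)

    def test_all_ones(self):
        m = combined_metrics(1, 1, 1)
        assert (m.f1, m.balanced_precision) == (1.0, 1.0)

    def test_zero_fitness_precision_convention(self):
        assert combined_metrics(0.0, 0.0, 0.0).f1 == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_recompute_to_1e12(self, f, p, b):
        m = combined_metrics(f, p, b)
        expected_f1 = 0.0 if f + p == 0 else 2 * f * p / (f + p)
        assert math.isclose(m.f1, expected_f1, abs_tol=1e-12)
        assert math.isclose(m.balanced_precision, (p + b) / 2, abs_tol=1e-12)


class TestStructuralMetrics:
    def test_never_replayed_generalization_zero(self, model):
        g, _ = structural_metrics(model, EventLog(()))
        assert g == 0.0

    def test_single_transition_simplicity_one(self):
        _, s = structural_metrics(NormativeModel(("Only",)), EventLog(()))
        assert s == 1.0

    def test_default_log_in_open_interval(self, model, default_log):
        g, s = structural_metrics(model, default_log)
        assert 0.0 < g < 1.0 and 0.0 < s < 1.0


class TestClassification:
    def test_canonical_trace_no_records(self, model):
        log = EventLog((make_trace("c", CANONICAL_ACTIVITIES),))
        recs = classify_deviations({"c": align_trace(log.traces[0], model)}, log, model)
        assert recs == []

    def test_injected_skips_recovered(self, default_log, model, alignments, records):
        """Single-skip variants are recovered with the exact missing activity."""
        by_case: dict[str, list] = {}
        for r in records:
            by_case.setdefault(r.case_id, []).append(r)
        checked = 0
        for t in default_log:
            injected = json.loads(t.meta["injected"])
            skips = [d for d in injected if d["type"] == "skipped_step"]
            if t.meta["variant"] in ("v06_skip_nurse", "v07_skip_record", "v09_skip_billing", "v10_skip_chemo"):
                got = [r for r in by_case.get(t.case_id, []) if r.type == "skipped_step"]
                assert {r.activities[0] for r in got} == {d["activities"][0] for d in skips}
                checked += 1
        assert checked >= 50

    def test_injected_loops_recovered_with_delay(self, default_log, records):
        by_case: dict[str, list] = {}
        for r in records:
            by_case.setdefault(r.case_id, []).append(r)
        checked = 0
        for t in default_log:
            injected = [d for d in json.loads(t.meta["injected"]) if d["type"] == "loop_rework"]
            if not injected:
                continue
            got = [r for r in by_case.get(t.case_id, []) if r.type == "loop_rework"]
            assert len(got) == len(injected)
            for g, d in zip(
                sorted(got, key=lambda r: r.segment), injected
            ):
                assert set(g.activities) == set(d["activities"])
                assert g.delay_hours == pytest.approx(d["delay_hours"], abs=0.05)
            checked += 1
        assert checked >= 30

    def test_injected_resequencing_recovered(self, default_log, records):
        by_case: dict[str, list] = {}
        for r in records:
            by_case.setdefault(r.case_id, []).append(r)
        for t in default_log:
            if t.meta["variant"] != "v11_resequenced":
                continue
            injected = json.loads(t.meta["injected"])[0]
            got = [r for r in by_case.get(t.case_id, []) if r.type == "resequenced"]
            assert len(got) == 1
            assert set(got[0].activities) <= set(injected["activities"])

    def test_truncated_cases_are_incomplete_not_deviant(self, default_log, records):
        deviant_ids = {r.case_id for r in records}
        for t in default_log:
            if t.meta["tags"] == "truncated":
                assert t.case_id not in deviant_ids


class TestDeviationSummary:
    def test_empty_records(self, default_log):
        s = deviation_summary([], default_log)
        assert (s.deviant_case_pct, s.loop_case_pct, s.mean_loop_delay_hours) == (0, 0, 0)

    def test_toy_share(self, model):
        log = EventLog(tuple(make_trace(f"c{i}", CANONICAL_ACTIVITIES) for i in range(10)))
        from pm2pim.conformance import DeviationRecord

        recs = [DeviationRecord(f"c{i}", "skipped_step", ("Billing",)) for i in range(3)]
        s = deviation_summary(recs, log)
        assert s.deviant_case_pct == pytest.approx(30.0)

    def test_default_log_summary_consistency(self, records, default_log):
        s = deviation_summary(records, default_log)
        assert 0 <= s.deviant_case_pct <= 100
        assert s.counts_per_type["loop_rework"] == 35
        assert s.loop_case_pct == pytest.approx(100 * 34 / 214)
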