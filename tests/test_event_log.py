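"""Event-log I/O and data-preparation rules."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm2pim.event_log import (
    ActivityDictionary,
    Event,
    EventLog,
    Trace,
    harmonize_activities,
    log_from_events,
    read_csv,
    read_xes,
    reconcile_case_ids,
    repair_timestamps,
    validate_log,
    write_csv,
    write_xes,
)
from pm2pim.normative_model import PERSIAN_TO_ENGLISH

T0 = datetime(2024, 3, 1, 8, 0, 0)


def _trace(case_id, labels, minutes=None):
    minutes = minutes or range(0, 10 * len(labels), 10)
    return Trace(
        case_id,
        tuple(Event(case_id, a, T0 + timedelta(minutes=m)) for a, m in zip(labels, minutes)),
    )


def _logs_equal(a: EventLog, b: EventLog) -> bool:
    if len(a) != len(b):
        return False
    for ta, tb in zip(a.traces, b.traces):
        if ta.case_id != tb.case_id or dict(ta.meta) != dict(tb.meta):
            return False
        for ea, eb in zip(ta.events, tb.events):
            if (ea.activity, ea.timestamp, ea.resource, dict(ea.extras)) != (
                eb.activity,
                eb.timestamp,
                eb.resource,
                dict(eb.extras),
            ):
                return False
    return True


class TestXes:
    def test_minimal_roundtrip(self, tmp_path):
        log = EventLog((_trace("c1", ["Admission", "Billing"]),))
        path = tmp_path / "m.xes"
        write_xes(log, path)
        back = read_xes(path)
        assert len(back) == 1 and len(back.traces[0]) == 2
        assert _logs_equal(log, back)

    def test_empty_log(self, tmp_path):
        path = tmp_path / "e.xes"
        write_xes(EventLog(()), path)
        back = read_xes(path)
        assert len(back) == 0 and back.vocabulary == frozenset()

    def test_generated_log_roundtrips_losslessly(self, tmp_path, default_log):
        path = tmp_path / "g.xes"
        write_xes(default_log, path)
        assert _logs_equal(default_log, read_xes(path))

    def test_extras_and_resource_survive(self, tmp_path):
        ev = Event("c1", "Admission", T0, resource="nurse-3", extras={"ward": "onc"})
        log = EventLog((Trace("c1", (ev,)),))
        path = tmp_path / "x.xes"
        write_xes(log, path)
        back = read_xes(path).traces[0].events[0]
        assert back.resource == "nurse-3" and back.extras["ward"] == "onc"

    def test_malformed_xml_raises(self, tmp_path):
        path = tmp_path / "bad.xes"
        path.write_text("<log><trace></log>")
        with pytest.raises(ValueError, match="malformed"):
            read_xes(path)

    def test_missing_timestamp_names_case(self, tmp_path):
        path = tmp_path / "mt.xes"
        path.write_text(
            '<log><trace><string key="concept:name" value="c9"/>'
            '<event><string key="concept:name" value="Admission"/></event></trace></log>'
        )
        with pytest.raises(ValueError, match="c9"):
            read_xes(path)


class TestCsv:
    def test_grouping_and_sorting(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "ReceptionID,ReceptionDate,ReceptionTime,ServiceName,Resource\n"
            "a,2024-03-01,09:00:00,Billing,\n"
            "b,2024-03-01,08:00:00,Admission,\n"
            "a,2024-03-01,08:00:00,Admission,\n"
        )
        log = read_csv(path)
        assert len(log) == 2
        trace_a = next(t for t in log.traces if t.case_id == "a")
        assert trace_a.activities == ("Admission", "Billing")  # internally sorted

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("id,when\n1,2024-01-01\n")
        with pytest.raises(KeyError, match="ReceptionID"):
            read_csv(path)

    def test_unparseable_row_names_row_number(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "ReceptionID,ReceptionDate,ReceptionTime,ServiceName,Resource\n"
            "a,not-a-date,09:00:00,Billing,\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_csv(path)

    def test_generated_log_roundtrips(self, tmp_path, default_log):
        path = tmp_path / "g.csv"
        write_csv(default_log, path)
        back = read_csv(path)
        assert len(back) == len(default_log) and back.n_events == default_log.n_events
        by_id = {t.case_id: t for t in back.traces}
        for t in default_log.traces:
            assert by_id[t.case_id].activities == t.activities
            assert [e.timestamp for e in by_id[t.case_id].events] == [
                e.timestamp for e in t.events
            ]


class TestHarmonize:
    def test_source_labels_become_canonical(self):
        log = EventLog((_trace("c1", ["paziresh"]),))
        out = harmonize_activities(log, ActivityDictionary(PERSIAN_TO_ENGLISH))
        assert out.traces[0].activities == ("Admission",)

    def test_identity_dictionary_is_noop(self, default_log):
        identity = ActivityDictionary({a: a for a in default_log.vocabulary})
        assert _logs_equal(default_log, harmonize_activities(default_log, identity))

    def test_strict_unknown_label_raises(self):
        log = EventLog((_trace("c1", ["mystery"]),))
        with pytest.raises(KeyError, match="mystery"):
            harmonize_activities(log, ActivityDictionary({"x": "y"}, "strict"))

    def test_lenient_passthrough_reported(self):
        log = EventLog((_trace("c1", ["mystery", "paziresh"]),))
        out = harmonize_activities(log, ActivityDictionary(PERSIAN_TO_ENGLISH, "lenient"))
        assert out.traces[0].activities == ("mystery", "Admission")
        assert "mystery" in out.meta["unmapped_labels"]

    def test_preserves_event_count_and_order(self, default_log):
        mapping = {a: a.upper() for a in default_log.vocabulary}
        out = harmonize_activities(default_log, ActivityDictionary(mapping))
        assert out.n_events == default_log.n_events
        for ta, tb in zip(default_log.traces, out.traces):
            assert [e.timestamp for e in ta.events] == [e.timestamp for e in tb.events]


class TestRepairTimestamps:
    def test_equal_minute_pair_respace(self):
        log = EventLog((_trace("c1", ["Admission", "Billing"], minutes=[0, 0]),))
        out = repair_timestamps(log)
        t = out.traces[0]
        assert t.events[1].timestamp - t.events[0].timestamp == timedelta(minutes=5)

    def test_strictly_increasing_unchanged(self, default_log):
        assert _logs_equal(default_log, repair_timestamps(default_log))

    def test_run_of_three_and_monotone(self):
        log = EventLog((_trace("c1", ["Admission", "Billing", "Chemotherapy"], minutes=[0, 0, 0]),))
        out = repair_timestamps(log)
        stamps = [e.timestamp for e in out.traces[0].events]
        assert stamps == [T0, T0 + timedelta(minutes=5), T0 + timedelta(minutes=10)]
        assert all(a < b for a, b in zip(stamps, stamps[1:]))

    def test_non_positive_offset_rejected(self):
        with pytest.raises(ValueError):
            repair_timestamps(EventLog(()), 0)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=8))
    def test_idempotent(self, minute_offsets):
        minutes = sorted(minute_offsets)
        log = EventLog((_trace("c1", ["A"] * 0 + ["Step"] * len(minutes), minutes=minutes),))
        once = repair_timestamps(log)
        twice = repair_timestamps(once)
        assert _logs_equal(once, twice)


class TestReconcile:
    def _rows(self):
        return [
            {"case_id": "a", "InsuranceID": "i1", "ReceptionDate": "d1", "ReceptionTime": "t1"},
            {"case_id": "", "InsuranceID": "i1", "ReceptionDate": "d1", "ReceptionTime": "t1"},
            {"case_id": "b", "InsuranceID": "i2", "ReceptionDate": "d2", "ReceptionTime": "t2"},
        ]

    def test_unique_match_recovers(self):
        kept, rep = reconcile_case_ids(self._rows())
        assert len(kept) == 3 and rep["n_recovered"] == 1
        assert kept[1]["case_id"] == "a"

    def test_no_match_dropped_and_counted(self):
        rows = self._rows()
        rows[1]["InsuranceID"] = "unknown"
        kept, rep = reconcile_case_ids(rows)
        assert len(kept) == 2 and rep["n_unresolved"] == 1

    def test_ambiguous_dropped(self):
        rows = self._rows()
        rows[2]["InsuranceID"], rows[2]["ReceptionDate"], rows[2]["ReceptionTime"] = "i1", "d1", "t1"
        kept, rep = reconcile_case_ids(rows)
        assert rep["n_ambiguous"] == 1 and len(kept) == 2

    def test_synthetic_blanking_fully_recovered(self, default_log):
        # blank ~2% of ids in multi-event cases; the insurance id keys the case
        rows = []
        for t in default_log.traces:
            for ev in t.events:
                rows.append(
                    {
                        "case_id": ev.case_id,
                        "InsuranceID": f"ins-{t.case_id}",
                        "row": len(rows),
                        "multi": len(t) > 1,
                    }
                )
        truth = {}
        for i in range(0, len(rows), 50):
            if rows[i]["multi"]:
                truth[rows[i]["row"]] = rows[i]["case_id"]
                rows[i] = dict(rows[i], case_id="")
        kept, rep = reconcile_case_ids(rows, fallback_keys=("InsuranceID",))
        assert rep["n_recovered"] == len(truth) and rep["n_unresolved"] == 0
        by_row = {r["row"]: r for r in kept}
        assert all(by_row[idx]["case_id"] == cid for idx, cid in truth.items())

    def test_never_invents_ids(self):
        rows = [{"case_id": "", "InsuranceID": "x", "ReceptionDate": "d", "ReceptionTime": "t"}]
        kept, rep = reconcile_case_ids(rows)
        assert kept == [] and rep["n_unresolved"] == 1


class TestValidate:
    def test_default_log_clean(self, default_log):
        rep = validate_log(default_log)
        assert (rep.n_cases, rep.n_events) == (214, 1254)
        assert rep.ok

    def test_decreasing_pair_flagged(self):
        t = Trace(
            "c1",
            (
                Event("c1", "Admission", T0 + timedelta(hours=2)),
                Event("c1", "Billing", T0),
            ),
        )
        rep = validate_log(EventLog((t,)))
        assert len(rep.issues) == 1 and rep.issues[0]["kind"] == "ordering"

    def test_empty_log_zero_counts(self):
        rep = validate_log(EventLog(()))
        assert (rep.n_cases, rep.n_events, rep.issues) == (0, 0, ())
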