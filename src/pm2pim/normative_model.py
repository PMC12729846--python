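"""The normative chemotherapy pathway: a strictly sequential workflow model.

The intended ("to-be") process is a chain of seven activities, from patient
admission through billing, chemotherapy preparation, the nurse/medication
basket step, injection, record handling (the re-approval/validation step) and
treatment completion.  Because the model is strictly sequential it can be
viewed as a workflow net that is a single place-transition chain, which is
how :func:`to_pnml` exports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from .event_log import EventLog, Trace

__all__ = [
    "NormativeModel",
    "CANONICAL_ACTIVITIES",
    "PERSIAN_TO_ENGLISH",
    "default_model",
    "default_dictionary_mapping",
    "is_full_adherent",
    "full_adherence_filter",
    "to_pnml",
]

#: Canonical seven-step sequence (English labels of the admission-to-completion pathway).
CANONICAL_ACTIVITIES: tuple[str, ...] = (
    "Admission",
    "Billing",
    "Chemotherapy",
    "Nurse and Medication Basket",
    "Injection",
    "Record Handling",
    "Treatment Completion",
)

#: Source-system (Persian transliteration) labels mapped to the canonical vocabulary.
PERSIAN_TO_ENGLISH: dict[str, str] = {
    "paziresh": "Admission",
    "sandugh": "Billing",
    "Shimi Darmani": "Chemotherapy",
    "Parastar and Sabad Daru": "Nurse and Medication Basket",
    "tazrigh": "Injection",
    "parvande": "Record Handling",
    "Etmam Darman": "Treatment Completion",
}


@dataclass(frozen=True)
class NormativeModel:
    """An ordered list of canonical activity labels with an approval subset.

    ``approval_class`` flags the validation/re-approval steps; skipping one of
    those is the clinically critical deviation class.  Record Handling is the
    default because it is the chart re-approval step between injection and
    treatment completion.
    """

    activities: tuple[str, ...] = CANONICAL_ACTIVITIES
    approval_class: frozenset[str] = field(default_factory=lambda: frozenset({"Record Handling"}))

    def __post_init__(self) -> None:
        if len(self.activities) == 0:
            raise ValueError("normative model needs at least one activity")
        if len(set(self.activities)) != len(self.activities):
            raise ValueError("normative model labels must be unique")

    def __len__(self) -> int:
        return len(self.activities)

    def index(self, activity: str) -> int:
        return self.activities.index(activity)

    def reversed(self) -> "NormativeModel":
        return NormativeModel(tuple(reversed(self.activities)), self.approval_class)


def default_model() -> NormativeModel:
    """The seven-activity sequential pathway with Record Handling as approval step."""
    return NormativeModel()


def default_dictionary_mapping() -> dict[str, str]:
    """Raw-label harmonization map: source-system names plus identity entries."""
    mapping = dict(PERSIAN_TO_ENGLISH)
    mapping.update({a: a for a in CANONICAL_ACTIVITIES})
    # common export suffix variants seen in frequency tables
    mapping.update({f"{a} event": a for a in CANONICAL_ACTIVITIES})
    mapping.update({f"{a} _event": a for a in CANONICAL_ACTIVITIES})
    return mapping


def is_full_adherent(trace: Trace, model: NormativeModel) -> bool:
    """Strict adherence: all activities present, no extras, canonical order.

    True iff the trace's activity sequence equals the model sequence exactly.
    """
    return trace.activities == tuple(model.activities)


def full_adherence_filter(log: EventLog, model: NormativeModel) -> tuple[EventLog, int]:
    """Keep exactly the strictly adherent traces (original order preserved)."""
    kept = tuple(t for t in log.traces if is_full_adherent(t, model))
    return EventLog(kept, dict(log.meta)), len(kept)


def to_pnml(model: NormativeModel, path) -> None:
    """Export the sequential workflow net as PNML.

    The net is a chain: place p0 (source, marked) -> t1 -> p1 -> ... -> tn ->
    pn (sink), with one labelled transition per activity, hence n transitions
    and n+1 places.
    """
    pnml = etree.Element("pnml")
    net = etree.SubElement(pnml, "net", id="normative", type="http://www.pnml.org/version-2009/grammar/ptnet")
    page = etree.SubElement(net, "page", id="page0")

    def add_place(pid: str, marked: bool) -> None:
        pl = etree.SubElement(page, "place", id=pid)
        if marked:
            mk = etree.SubElement(pl, "initialMarking")
            etree.SubElement(mk, "text").text = "1"

    add_place("p0", marked=True)
    for i, activity in enumerate(model.activities, start=1):
        tr = etree.SubElement(page, "transition", id=f"t{i}")
        name = etree.SubElement(tr, "name")
        etree.SubElement(name, "text").text = activity
        add_place(f"p{i}", marked=False)
        etree.SubElement(page, "arc", id=f"a{2 * i - 1}", source=f"p{i - 1}", target=f"t{i}")
        etree.SubElement(page, "arc", id=f"a{2 * i}", source=f"t{i}", target=f"p{i}")
    etree.ElementTree(pnml).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
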