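"""Interpretation records: findings, phenotype inference and reporting.

This module is the Evaluation-archetype side of the pipeline.  The rule
base produces one :class:`Finding` per scale element (ontology class +
severity level + optional laterality).  Non-absent findings are mapped
onto the most specific matching ontology class (e.g. a *mild, left*
finding on ``limb_dysmetria`` asserts ``mild_left_limb_dysmetria``) and
the named-class subsumption closure yields the patient's inferred
phenotype set: a severe standing- and sitting-instability pattern, for
example, entails ataxic postural instability and hence truncal ataxia.

On top of the closure, :func:`build_synopsis` summarizes the three
clinical dimensions (midline/truncal ataxia, speech, appendicular ataxia
per side, with an asymmetry flag) and :func:`render_report` emits the
deterministic text / JSON / XML / graph artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

from .errors import ParseError, UnknownClassError, ValidationError
from .ontology import PhenotypeOntology, SEVERITY_LEVELS
from .scale import DerivedScores

#: ordinal severity scale used for aggregation and monotonicity checks.
#: ``None`` marks a terminal class (abasia, astasia, anarthria), ranked
#: above ``severe`` like ``profound``.
SEVERITY_RANK = {"absent": 0, "borderline": 1, "mild": 2,
                 "moderate": 3, "severe": 4, "profound": 5}
_RANK_TO_LABEL = {v: k for k, v in SEVERITY_RANK.items()}

SYNDROME_CATEGORIES = ("absent", "mild", "moderate", "severe", "very severe")
#: severity qualifier used when asserting the syndrome class itself
_CATEGORY_SEVERITY = {"mild": "mild", "moderate": "moderate",
                      "severe": "severe", "very severe": "profound"}


def severity_rank(severity: str | None) -> int:
    """Rank of a finding severity; terminal classes (None) rank as profound."""
    if severity is None:
        return SEVERITY_RANK["profound"]
    try:
        return SEVERITY_RANK[severity]
    except KeyError:
        raise ValidationError(f"unknown severity {severity!r}") from None


@dataclass(frozen=True)
class Finding:
    """One interpreted scale element.

    ``severity`` is a level from the defined order, ``"absent"`` for an
    explicit normal finding, or ``None`` when the score maps to a
    terminal class of its own (e.g. gait 8 -> abasia).
    """

    element: str
    onto_class: str
    severity: str | None
    laterality: str | None = None

    def __post_init__(self):
        if self.severity is not None and self.severity != "absent" \
                and self.severity not in SEVERITY_LEVELS:
            raise ValidationError(
                f"finding {self.element!r}: bad severity {self.severity!r}")

    @property
    def rank(self) -> int:
        return severity_rank(self.severity)

    @property
    def absent(self) -> bool:
        return self.severity == "absent"


@dataclass(frozen=True)
class SyndromeAssessment:
    """Categorical cerebellar-syndrome assessment derived from the total."""

    category: str
    total: float

    def __post_init__(self):
        if self.category not in SYNDROME_CATEGORIES:
            raise ValidationError(
                f"unknown syndrome category {self.category!r}")


@dataclass(frozen=True)
class SynopsisFeature:
    """Presence + worst severity of one clinical dimension (per side)."""

    name: str
    onto_class: str
    present: bool
    severity: str  # label from the ordinal scale ('absent' .. 'profound')
    laterality: str | None = None

    @property
    def rank(self) -> int:
        return SEVERITY_RANK[self.severity]


@dataclass(frozen=True)
class Synopsis:
    features: tuple[SynopsisFeature, ...]
    asymmetry: bool

    def feature(self, name: str, laterality: str | None = None) -> SynopsisFeature:
        for f in self.features:
            if f.name == name and f.laterality == laterality:
                return f
        raise KeyError((name, laterality))


@dataclass(frozen=True)
class EvaluationRecord:
    """Aggregated interpretation of one observation.

    ``findings`` groups the per-item findings by cluster; ``inferred``
    is the subsumption closure over all asserted classes (including the
    syndrome class when the syndrome is present).
    """

    patient_id: str
    date: str
    derived: DerivedScores
    findings: dict[str, tuple[Finding, ...]]
    assessment: SyndromeAssessment
    inferred: frozenset[str] = frozenset()
    synopsis: Synopsis | None = None
    report: str = ""
    trace: tuple[str, ...] = ()

    def all_findings(self) -> list[Finding]:
        return [f for cluster in sorted(self.findings)
                for f in self.findings[cluster]]


# ----------------------------------------------------------------------
# phenotype inference
# ----------------------------------------------------------------------

def asserted_class_for(ont: PhenotypeOntology, finding: Finding) -> str | None:
    """Most specific ontology class a finding asserts (None when absent).

    Resolution tries, in order, ``<severity>_<side>_<class>``,
    ``<severity>_<class>``, ``<side>_<class>`` and finally the bound
    class itself, so severity/laterality subclasses are used whenever
    the ontology defines them.
    """
    if finding.onto_class not in ont:
        raise UnknownClassError([finding.onto_class], context="finding")
    if finding.absent:
        return None
    candidates = []
    sev, side, cls = finding.severity, finding.laterality, finding.onto_class
    if sev and side:
        candidates.append(f"{sev}_{side}_{cls}")
    if sev:
        candidates.append(f"{sev}_{cls}")
    if side:
        candidates.append(f"{side}_{cls}")
    candidates.append(cls)
    for cand in candidates:
        if cand in ont:
            return cand
    return cls


def syndrome_finding(assessment: SyndromeAssessment) -> Finding | None:
    """Finding asserting the cerebellar-syndrome class (None when absent)."""
    if assessment.category == "absent":
        return None
    return Finding(element="cerebellar_syndrome",
                   onto_class="cerebellar_syndrome",
                   severity=_CATEGORY_SEVERITY[assessment.category])


def infer_phenotypes(ont: PhenotypeOntology, findings) -> set[str]:
    """Subsumption closure over the classes asserted by non-absent findings."""
    asserted = {c for f in findings
                if (c := asserted_class_for(ont, f)) is not None}
    return ont.classify_individual(asserted) if asserted else set()


# ----------------------------------------------------------------------
# synopsis
# ----------------------------------------------------------------------

DEFAULT_CLUSTER_BINDINGS = {
    "gait_and_balance": "truncal_ataxia",
    "speech_disturbance": "dysarthria",
    "limb_coordination": "appendicular_ataxia",
}

#: left/right severity-rank difference at which asymmetry is flagged
DEFAULT_ASYMMETRY_THRESHOLD = 2


def _aggregate(findings) -> tuple[bool, str]:
    """Cluster aggregation: present iff any member non-absent; worst wins.

    Terminal-class findings (abasia, astasia, anarthria) count as
    ``severe`` here: the dimension grading runs absent..severe, with
    ``profound`` reserved for findings explicitly graded so.
    """
    findings = list(findings)
    if not findings:
        return False, "absent"
    worst = max(min(f.rank, SEVERITY_RANK["severe"])
                if f.severity is None else f.rank
                for f in findings)
    return worst > 0, _RANK_TO_LABEL[worst]


def build_synopsis(record: EvaluationRecord, ont: PhenotypeOntology,
                   cluster_bindings=None,
                   asymmetry_threshold: int = DEFAULT_ASYMMETRY_THRESHOLD,
                   ) -> Synopsis:
    """Per-dimension summary of an evaluation.

    Midline (truncal) ataxia aggregates the gait/stance/sitting findings,
    speech the dysarthria finding, and appendicular ataxia the four limb
    findings of each side separately; each dimension reports presence and
    the maximum member severity.  Asymmetry is flagged when the left and
    right appendicular severity ranks differ by at least
    ``asymmetry_threshold`` ordinal steps.
    """
    bindings = dict(cluster_bindings or DEFAULT_CLUSTER_BINDINGS)
    for cls in bindings.values():
        if cls not in ont:
            raise UnknownClassError([cls], context="cluster bindings")

    midline = _aggregate(record.findings.get("gait_and_balance", ()))
    speech = _aggregate(record.findings.get("speech_disturbance", ()))
    limb = record.findings.get("limb_coordination", ())
    right = _aggregate(f for f in limb if f.laterality == "right")
    left = _aggregate(f for f in limb if f.laterality == "left")

    features = (
        SynopsisFeature("midline_ataxia", bindings["gait_and_balance"],
                        *midline),
        SynopsisFeature("speech_impairment", bindings["speech_disturbance"],
                        *speech),
        SynopsisFeature("appendicular_ataxia", bindings["limb_coordination"],
                        *right, laterality="right"),
        SynopsisFeature("appendicular_ataxia", bindings["limb_coordination"],
                        *left, laterality="left"),
    )
    asymmetry = abs(SEVERITY_RANK[right[1]] - SEVERITY_RANK[left[1]]) \
        >= asymmetry_threshold
    return Synopsis(features=features, asymmetry=asymmetry)


# ----------------------------------------------------------------------
# reporting / export
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ReportBundle:
    """All render targets for one evaluation (pure function of the record)."""

    text: str
    payload: dict
    xml: str
    graph: dict | None = None
    dot: str | None = None


def _feature_line(f: SynopsisFeature) -> str:
    side = f" ({f.laterality} side)" if f.laterality else ""
    if not f.present:
        return f"  - {f.name.replace('_', ' ')}{side}: not present"
    return f"  - {f.name.replace('_', ' ')}{side}: present, severity {f.severity}"


def render_text(record: EvaluationRecord, ont: PhenotypeOntology | None = None,
                ) -> str:
    """Deterministic plain-text report (assessment + synopsis + findings)."""
    lines = [
        "SARA assessment report",
        f"Patient: {record.patient_id}    Date: {record.date}",
        f"Total SARA score: {record.derived.total:g} / 40",
        f"Cerebellar syndrome: {record.assessment.category}",
        "",
        "Clinical synopsis:",
    ]
    if record.synopsis is None or not any(
            f.present for f in record.synopsis.features):
        lines.append("  - no phenotypic abnormalities detected")
    else:
        lines.extend(_feature_line(f) for f in record.synopsis.features)
        if record.synopsis.asymmetry:
            lines.append("  - marked left-right asymmetry of limb coordination")
    lines.append("")
    lines.append("Item findings:")
    for finding in record.all_findings():
        side = f" [{finding.laterality}]" if finding.laterality else ""
        if finding.absent:
            desc = f"no abnormality ({finding.onto_class})"
        elif finding.severity is None:
            desc = finding.onto_class
        else:
            desc = f"{finding.severity} {finding.onto_class}"
        lines.append(f"  {finding.element}{side}: {desc}")
    lines.append("")
    lines.append("Inferred phenotypic abnormalities:")
    if not record.inferred:
        lines.append("  (none)")
    else:
        for cid in sorted(record.inferred):
            label = ont[cid].label if ont is not None and cid in ont else cid
            lines.append(f"  {cid}: {label}")
    return "\n".join(lines) + "\n"


def record_to_dict(record: EvaluationRecord) -> dict:
    """JSON-ready dictionary of the full evaluation (stable ordering)."""
    return {
        "patient_id": record.patient_id,
        "date": record.date,
        "derived": {
            "means": {k: record.derived.means[k]
                      for k in sorted(record.derived.means)},
            "total": record.derived.total,
        },
        "assessment": {"category": record.assessment.category,
                       "total": record.assessment.total},
        "findings": {
            cluster: [
                {"element": f.element, "onto_class": f.onto_class,
                 "severity": f.severity, "laterality": f.laterality}
                for f in record.findings[cluster]
            ]
            for cluster in sorted(record.findings)
        },
        "inferred": sorted(record.inferred),
        "synopsis": None if record.synopsis is None else {
            "features": [
                {"name": f.name, "onto_class": f.onto_class,
                 "present": f.present, "severity": f.severity,
                 "laterality": f.laterality}
                for f in record.synopsis.features
            ],
            "asymmetry": record.synopsis.asymmetry,
        },
        "trace": list(record.trace),
    }


def record_to_json(record: EvaluationRecord) -> str:
    return json.dumps(record_to_dict(record), indent=2, sort_keys=True)


def evaluation_to_xml(record: EvaluationRecord) -> str:
    """Lossless XML payload; :func:`evaluation_from_xml` inverts it."""
    root = ET.Element("evaluation", patient_id=record.patient_id,
                      date=record.date)
    derived = ET.SubElement(root, "derived", total=repr(record.derived.total))
    for item in sorted(record.derived.means):
        ET.SubElement(derived, "mean", item=item,
                      value=repr(record.derived.means[item]))
    ET.SubElement(root, "assessment", category=record.assessment.category,
                  total=repr(record.assessment.total))
    findings = ET.SubElement(root, "findings")
    for cluster in sorted(record.findings):
        cl = ET.SubElement(findings, "cluster", name=cluster)
        for f in record.findings[cluster]:
            attrs = {"element": f.element, "onto_class": f.onto_class}
            if f.severity is not None:
                attrs["severity"] = f.severity
            if f.laterality is not None:
                attrs["laterality"] = f.laterality
            ET.SubElement(cl, "finding", attrs)
    inferred = ET.SubElement(root, "inferred")
    for cid in sorted(record.inferred):
        ET.SubElement(inferred, "class", id=cid)
    if record.synopsis is not None:
        syn = ET.SubElement(root, "synopsis",
                            asymmetry=str(record.synopsis.asymmetry).lower())
        for f in record.synopsis.features:
            attrs = {"name": f.name, "onto_class": f.onto_class,
                     "present": str(f.present).lower(),
                     "severity": f.severity}
            if f.laterality is not None:
                attrs["laterality"] = f.laterality
            ET.SubElement(syn, "feature", attrs)
    trace = ET.SubElement(root, "trace")
    for rule_id in record.trace:
        ET.SubElement(trace, "rule", id=rule_id)
    report = ET.SubElement(root, "report")
    report.text = record.report
    return ET.tostring(root, encoding="unicode")


def evaluation_from_xml(text: str) -> EvaluationRecord:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"bad evaluation XML: {exc}") from exc
    derived_el = root.find("derived")
    derived = DerivedScores(
        means={m.get("item"): float(m.get("value"))
               for m in derived_el.findall("mean")},
        total=float(derived_el.get("total")),
    )
    assess_el = root.find("assessment")
    assessment = SyndromeAssessment(category=assess_el.get("category"),
                                    total=float(assess_el.get("total")))
    findings = {}
    for cl in root.find("findings").findall("cluster"):
        findings[cl.get("name")] = tuple(
            Finding(element=f.get("element"), onto_class=f.get("onto_class"),
                    severity=f.get("severity"), laterality=f.get("laterality"))
            for f in cl.findall("finding")
        )
    inferred = frozenset(c.get("id") for c in root.find("inferred"))
    synopsis = None
    syn_el = root.find("synopsis")
    if syn_el is not None:
        synopsis = Synopsis(
            features=tuple(
                SynopsisFeature(name=f.get("name"),
                                onto_class=f.get("onto_class"),
                                present=f.get("present") == "true",
                                severity=f.get("severity"),
                                laterality=f.get("laterality"))
                for f in syn_el.findall("feature")
            ),
            asymmetry=syn_el.get("asymmetry") == "true",
        )
    trace = tuple(r.get("id") for r in root.find("trace"))
    report = root.find("report").text or ""
    return EvaluationRecord(
        patient_id=root.get("patient_id"), date=root.get("date"),
        derived=derived, findings=findings, assessment=assessment,
        inferred=inferred, synopsis=synopsis, report=report, trace=trace,
    )


def render_report(record: EvaluationRecord,
                  ont: PhenotypeOntology | None = None) -> ReportBundle:
    """Render every export artifact for one evaluation.

    The node-link graph and DOT renderings (the phenotype-graph view of
    the inferred closure) require the ontology and are omitted when it
    is not supplied.
    """
    graph = dot = None
    if ont is not None and record.inferred:
        graph = ont.to_node_link(restrict=record.inferred)
        dot = ont.to_dot(restrict=record.inferred)
    return ReportBundle(
        text=record.report or render_text(record, ont),
        payload=record_to_dict(record),
        xml=evaluation_to_xml(record),
        graph=graph,
        dot=dot,
    )
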