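"""Declarative rule base for interpreting SARA observations.

Three rule families fire in a fixed stage order, mirroring the
information-processing units of a guideline-style (GDL-like) clinical
rule set:

``calculation``
    arithmetic over observation elements: the four bilateral side-means
    and the total score (five rules);
``severity``
    per-item cut-off rules translating each raw score into a graded
    finding (an ontology class plus a severity level), per side for the
    bilateral items so lateralized findings exist downstream;
``assessment``
    heuristic banding of the total score into a categorical
    cerebellar-syndrome assessment.

Rules are data, not code: the whole base serializes to YAML/JSON, and
cut-off tables can be overridden from config, with disjointness and
coverage of every reachable score enforced at build time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError, ParseError, ValidationError
from .scale import (
    BILATERAL_ITEMS,
    CLUSTERS,
    DerivedScores,
    ObservationRecord,
    ScaleDefinition,
)
from .synopsis import (
    EvaluationRecord,
    Finding,
    SYNDROME_CATEGORIES,
    SyndromeAssessment,
    build_synopsis,
    infer_phenotypes,
    render_text,
    syndrome_finding,
)

STAGES = ("calculation", "severity", "assessment")
COMPARATORS = ("==", "<=", ">=", "<", ">", "between")


@dataclass(frozen=True)
class Condition:
    """A single comparison on an element; ``between`` is inclusive."""

    element: str
    comparator: str
    value: object

    def __post_init__(self):
        if self.comparator not in COMPARATORS:
            raise ConfigError(f"unknown comparator {self.comparator!r}")

    def holds(self, env: dict) -> bool:
        if self.element not in env:
            raise ValidationError(f"condition element {self.element!r} "
                                  "not available at this stage")
        x = env[self.element]
        op, v = self.comparator, self.value
        if op == "==":
            return x == v
        if op == "<=":
            return x <= v
        if op == ">=":
            return x >= v
        if op == "<":
            return x < v
        if op == ">":
            return x > v
        lo, hi = v
        return lo <= x <= hi


@dataclass(frozen=True)
class ComputeAction:
    """Write ``op(operands)`` (mean or sum over elements) to ``target``."""

    target: str
    op: str
    operands: tuple[str, ...]

    def __post_init__(self):
        if self.op not in ("mean", "sum"):
            raise ConfigError(f"unknown compute op {self.op!r}")

    def evaluate(self, env: dict) -> float:
        values = [env[e] for e in self.operands]
        total = float(sum(values))
        return total / len(values) if self.op == "mean" else total


@dataclass(frozen=True)
class FindingAction:
    """Assert a graded finding for an evaluation element."""

    element: str
    onto_class: str
    severity: str | None  # level, 'absent', or None for a terminal class
    laterality: str | None = None

    def to_finding(self) -> Finding:
        return Finding(element=self.element, onto_class=self.onto_class,
                       severity=self.severity, laterality=self.laterality)


@dataclass(frozen=True)
class AssessAction:
    """Assign the categorical cerebellar-syndrome assessment."""

    category: str

    def __post_init__(self):
        if self.category not in SYNDROME_CATEGORIES:
            raise ConfigError(f"unknown syndrome category {self.category!r}")


@dataclass(frozen=True)
class Rule:
    rule_id: str
    stage: str
    conditions: tuple[Condition, ...]
    action: ComputeAction | FindingAction | AssessAction

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")

    def matches(self, env: dict) -> bool:
        return all(c.holds(env) for c in self.conditions)


@dataclass(frozen=True)
class RuleBase:
    name: str
    version: str
    rules: tuple[Rule, ...]

    def stage(self, stage: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.stage == stage)

    @property
    def calculation_rules(self):
        return self.stage("calculation")

    @property
    def severity_rules(self):
        return self.stage("severity")

    @property
    def assessment_rules(self):
        return self.stage("assessment")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def action_dict(a):
            d = asdict(a)
            d["kind"] = type(a).__name__
            if "operands" in d:
                d["operands"] = list(d["operands"])
            return d

        return {
            "name": self.name,
            "version": self.version,
            "rules": [
                {
                    "rule_id": r.rule_id,
                    "stage": r.stage,
                    "conditions": [
                        {"element": c.element, "comparator": c.comparator,
                         "value": list(c.value)
                         if isinstance(c.value, tuple) else c.value}
                        for c in r.conditions
                    ],
                    "action": action_dict(r.action),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleBase":
        kinds = {"ComputeAction": ComputeAction,
                 "FindingAction": FindingAction,
                 "AssessAction": AssessAction}
        rules = []
        try:
            for rd in data["rules"]:
                conditions = tuple(
                    Condition(
                        element=cd["element"], comparator=cd["comparator"],
                        value=tuple(cd["value"])
                        if isinstance(cd["value"], list) else cd["value"])
                    for cd in rd["conditions"]
                )
                ad = dict(rd["action"])
                kind = kinds[ad.pop("kind")]
                if "operands" in ad:
                    ad["operands"] = tuple(ad["operands"])
                rules.append(Rule(rule_id=rd["rule_id"], stage=rd["stage"],
                                  conditions=conditions, action=kind(**ad)))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed rule base: {exc}") from exc
        return cls(name=data.get("name", "rulebase"),
                   version=data.get("version", "0"), rules=tuple(rules))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RuleBase":
        try:
            data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise ParseError(f"cannot parse rule base {path}: {exc}") from exc
        return cls.from_dict(data)


# ----------------------------------------------------------------------
# default SARA rule content
# ----------------------------------------------------------------------

#: Default severity cut-off table.  The published anchors are honored
#: (sitting 4 -> severe; gait 8 -> abasia; stance 6 -> astasia; speech
#: 6 -> anarthria); the remaining bins follow an even grading and can be
#: replaced wholesale from a config file.
DEFAULT_CUTOFFS: dict[str, list[dict]] = {
    "gait": [
        {"min": 0, "max": 0, "severity": "absent"},
        {"min": 1, "max": 2, "severity": "mild"},
        {"min": 3, "max": 5, "severity": "moderate"},
        {"min": 6, "max": 7, "severity": "severe"},
        {"min": 8, "max": 8, "class": "abasia"},
    ],
    "stance": [
        {"min": 0, "max": 0, "severity": "absent"},
        {"min": 1, "max": 2, "severity": "mild"},
        {"min": 3, "max": 4, "severity": "moderate"},
        {"min": 5, "max": 5, "severity": "severe"},
        {"min": 6, "max": 6, "class": "astasia"},
    ],
    "sitting": [
        {"min": 0, "max": 0, "severity": "absent"},
        {"min": 1, "max": 1, "severity": "mild"},
        {"min": 2, "max": 3, "severity": "moderate"},
        {"min": 4, "max": 4, "severity": "severe"},
    ],
    "speech": [
        {"min": 0, "max": 0, "severity": "absent"},
        {"min": 1, "max": 2, "severity": "mild"},
        {"min": 3, "max": 4, "severity": "moderate"},
        {"min": 5, "max": 5, "severity": "severe"},
        {"min": 6, "max": 6, "class": "anarthria"},
    ],
}
_LIMB_CUTOFFS = [
    {"min": 0, "max": 0, "severity": "absent"},
    {"min": 1, "max": 1, "severity": "mild"},
    {"min": 2, "max": 3, "severity": "moderate"},
    {"min": 4, "max": 4, "severity": "severe"},
]
for _item in BILATERAL_ITEMS:
    DEFAULT_CUTOFFS[_item] = [dict(seg) for seg in _LIMB_CUTOFFS]

#: Default cerebellar-syndrome banding of the total score T: T <= 1 is
#: treated as no syndrome (healthy controls score about 0.4 +/- 1.1 on
#: the SARA), then (1,10] mild, (10,20] moderate, (20,30] severe and
#: (30,40] very severe.  Not a standardized grading; config-overridable.
DEFAULT_SYNDROME_BANDS: list[dict] = [
    {"category": "absent", "max": 1},
    {"category": "mild", "min": 1, "max": 10},
    {"category": "moderate", "min": 10, "max": 20},
    {"category": "severe", "min": 20, "max": 30},
    {"category": "very severe", "min": 30},
]


def _severity_rules_for(item, side, segments) -> list[Rule]:
    element = item.item_id if side == "none" else f"{item.item_id}.{side}"
    laterality = None if side == "none" else side
    rules = []
    for seg in segments:
        lo, hi = seg["min"], seg["max"]
        if "class" in seg:
            onto_class, severity = seg["class"], None
        else:
            onto_class, severity = item.binding, seg["severity"]
        condition = (Condition(element, "==", lo) if lo == hi
                     else Condition(element, "between", (lo, hi)))
        rules.append(Rule(
            rule_id=f"sev.{element}.{lo}_{hi}",
            stage="severity",
            conditions=(condition,),
            action=FindingAction(element=element, onto_class=onto_class,
                                 severity=severity, laterality=laterality),
        ))
    return rules


def _check_cutoffs(item, segments) -> None:
    """Disjointness + exhaustiveness of one item's cut-off table."""
    hits = {s: 0 for s in item.score_range}
    for seg in segments:
        try:
            lo, hi = int(seg["min"]), int(seg["max"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(
                f"item {item.item_id!r}: malformed cut-off segment "
                f"{seg!r}") from exc
        if "class" not in seg and seg.get("severity") not in \
                ("absent", "borderline", "mild", "moderate", "severe",
                 "profound"):
            raise ConfigError(
                f"item {item.item_id!r}: segment {seg!r} needs a valid "
                "'severity' or a 'class'")
        for s in range(lo, hi + 1):
            if s not in hits:
                raise ConfigError(
                    f"item {item.item_id!r}: cut-off segment [{lo},{hi}] "
                    f"exceeds score range "
                    f"[{item.min_score},{item.max_score}]")
            hits[s] += 1
    uncovered = [s for s, n in hits.items() if n == 0]
    overlapped = [s for s, n in hits.items() if n > 1]
    if uncovered or overlapped:
        raise ConfigError(
            f"item {item.item_id!r}: cut-off table invalid "
            f"(uncovered scores {uncovered}, overlapping scores {overlapped})"
        )


def _check_bands(bands) -> None:
    """Band list must partition [0, 40] with contiguous half-open bands."""
    prev_hi = 0.0
    for i, band in enumerate(bands):
        if band.get("category") not in SYNDROME_CATEGORIES:
            raise ConfigError(f"band {band!r}: unknown category")
        lo = float(band.get("min", 0.0))
        hi = float(band.get("max", 40.0))
        if i == 0 and lo != 0.0:
            raise ConfigError("first syndrome band must start at 0")
        if i > 0 and lo != prev_hi:
            raise ConfigError(
                f"syndrome bands not contiguous at {lo} (previous ended "
                f"at {prev_hi})")
        if hi <= lo and not (i == 0 and hi == lo == 0.0):
            raise ConfigError(f"band {band!r}: empty interval")
        prev_hi = hi
    if prev_hi != 40.0:
        raise ConfigError("last syndrome band must end at 40")


def build_sara_rulebase(scale: ScaleDefinition,
                        cutoff_overrides: dict | None = None,
                        syndrome_bands: list | None = None) -> RuleBase:
    """Build the default SARA rule base.

    ``cutoff_overrides`` replaces the cut-off table of the named items
    (e.g. a full supplementary rule table can be dropped in);
    ``syndrome_bands`` replaces the total-score banding.  Both are
    validated: cut-offs must cover every reachable score exactly once,
    bands must partition [0, 40].
    """
    cutoffs = {k: [dict(s) for s in v] for k, v in DEFAULT_CUTOFFS.items()}
    for item_id, segments in (cutoff_overrides or {}).items():
        if item_id not in cutoffs:
            raise ConfigError(f"cut-off override for unknown item {item_id!r}")
        cutoffs[item_id] = [dict(s) for s in segments]
    bands = [dict(b) for b in (syndrome_bands or DEFAULT_SYNDROME_BANDS)]

    rules: list[Rule] = []
    # calculation stage: one mean per bilateral item + the total
    total_operands: list[str] = []
    for item in scale.items:
        if item.bilateral:
            rules.append(Rule(
                rule_id=f"calc.{item.item_id}.mean",
                stage="calculation",
                conditions=(),
                action=ComputeAction(
                    target=f"{item.item_id}.mean", op="mean",
                    operands=(f"{item.item_id}.right",
                              f"{item.item_id}.left")),
            ))
            total_operands.append(f"{item.item_id}.mean")
        else:
            total_operands.append(item.item_id)
    rules.append(Rule(
        rule_id="calc.total", stage="calculation", conditions=(),
        action=ComputeAction(target="total", op="sum",
                             operands=tuple(total_operands)),
    ))

    # severity stage: cut-off rules per item (per side when bilateral)
    for item in scale.items:
        _check_cutoffs(item, cutoffs[item.item_id])
        for side in item.sides:
            rules.extend(_severity_rules_for(item, side,
                                             cutoffs[item.item_id]))

    # assessment stage: total-score banding
    _check_bands(bands)
    for i, band in enumerate(bands):
        conditions = []
        if i > 0:
            conditions.append(Condition("total", ">", float(band["min"])))
        if "max" in band:
            conditions.append(Condition("total", "<=", float(band["max"])))
        rules.append(Rule(
            rule_id=f"assess.{band['category'].replace(' ', '_')}",
            stage="assessment",
            conditions=tuple(conditions),
            action=AssessAction(category=band["category"]),
        ))

    return RuleBase(name="sara-default", version="1", rules=tuple(rules))


# ----------------------------------------------------------------------
# rule execution
# ----------------------------------------------------------------------

def observation_env(obs: ObservationRecord) -> dict:
    """Observation-level element environment (raw scores)."""
    env = {}
    for (item_id, side), value in obs.scores.items():
        key = item_id if side == "none" else f"{item_id}.{side}"
        env[key] = value
    return env


def apply_calculation_rules(rb: RuleBase, obs: ObservationRecord,
                            trace: list | None = None) -> DerivedScores:
    """Fire the calculation stage: bilateral means and the total score."""
    env = observation_env(obs)
    means = {}
    # rules may be listed in any order: fire each as soon as its operands
    # are available (the total depends on the bilateral means)
    pending = [r for r in rb.calculation_rules if r.matches(env)]
    progress = True
    while pending and progress:
        progress = False
        for rule in list(pending):
            if any(op not in env for op in rule.action.operands):
                continue
            value = rule.action.evaluate(env)
            env[rule.action.target] = value
            if rule.action.target.endswith(".mean"):
                means[rule.action.target.rsplit(".", 1)[0]] = value
            if trace is not None:
                trace.append(rule.rule_id)
            pending.remove(rule)
            progress = True
    if pending:
        raise ValidationError(
            "calculation rules with unresolvable operands: "
            + ", ".join(r.rule_id for r in pending))
    if "total" not in env:
        raise ValidationError("calculation stage produced no total score")
    return DerivedScores(means=means, total=env["total"])


def apply_severity_rules(rb: RuleBase, obs: ObservationRecord,
                         derived: DerivedScores,
                         trace: list | None = None) -> list[Finding]:
    """Fire the severity stage: one graded finding per item (and side).

    A valid rule base covers every reachable score exactly once; an
    uncovered or doubly-covered score (possible only with a hand-edited
    serialized rule base) raises a ValidationError.
    """
    env = observation_env(obs)
    env.update({f"{k}.mean": v for k, v in derived.means.items()})
    env["total"] = derived.total
    by_element: dict[str, Finding] = {}
    for rule in rb.severity_rules:
        if not rule.matches(env):
            continue
        element = rule.action.element
        if element in by_element:
            raise ValidationError(
                f"severity rules overlap on element {element!r}")
        by_element[element] = rule.action.to_finding()
        if trace is not None:
            trace.append(rule.rule_id)
    expected = {e for r in rb.severity_rules for e in [r.action.element]}
    uncovered = sorted(e for e in expected if e not in by_element
                       and e in env)
    if uncovered:
        raise ValidationError(
            f"no severity rule matched element(s): {', '.join(uncovered)}")
    # deterministic element order: observation slot order
    ordered = [k for k in env if k in by_element]
    return [by_element[k] for k in ordered]


def apply_assessment_rules(rb: RuleBase, derived: DerivedScores,
                           trace: list | None = None) -> SyndromeAssessment:
    """Fire the assessment stage: band the total score."""
    env = {"total": derived.total}
    matched = [r for r in rb.assessment_rules if r.matches(env)]
    if len(matched) != 1:
        raise ValidationError(
            f"total {derived.total} matched {len(matched)} assessment "
            "rules (expected exactly 1)")
    if trace is not None:
        trace.append(matched[0].rule_id)
    return SyndromeAssessment(category=matched[0].action.category,
                              total=derived.total)


def run_pipeline(scale: ScaleDefinition, rb: RuleBase, ont,
                 obs: ObservationRecord) -> EvaluationRecord:
    """Run all stages on one observation and assemble the evaluation.

    Stages fire in the fixed order calculation -> severity -> assessment,
    then the phenotype closure is inferred over the asserted findings
    (plus the syndrome class when present) and the synopsis and textual
    report are composed.  The function is deterministic: identical
    inputs produce identical records, including the fired-rule trace.
    """
    scale.resolve_bindings(ont)
    trace: list[str] = []
    derived = apply_calculation_rules(rb, obs, trace=trace)
    findings = apply_severity_rules(rb, obs, derived, trace=trace)
    assessment = apply_assessment_rules(rb, derived, trace=trace)

    grouped = {cluster: tuple(
        f for f in findings
        if scale.item(f.element.split(".")[0]).cluster == cluster)
        for cluster in CLUSTERS}

    asserted = list(findings)
    syndrome = syndrome_finding(assessment)
    if syndrome is not None:
        asserted.append(syndrome)
    inferred = frozenset(infer_phenotypes(ont, asserted))

    record = EvaluationRecord(
        patient_id=obs.patient_id, date=obs.date, derived=derived,
        findings=grouped, assessment=assessment, inferred=inferred,
        trace=tuple(trace),
    )
    record = replace(record, synopsis=build_synopsis(
        record, ont, cluster_bindings=scale.cluster_bindings))
    return replace(record, report=render_text(record, ont))
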