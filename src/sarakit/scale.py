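"""SARA content model: items, score ranges, clusters and ontology bindings.

The SARA rates cerebellar ataxia through 8 motor items — gait, stance,
sitting, speech disturbance, and four limb-coordination tests scored once
per side.  The side scores of the bilateral items are averaged and the
four means added to the four axial scores, giving a total between 0 (no
ataxia) and 40 (most severe ataxia).

The :class:`ScaleDefinition` plays the role of a clinical Observation
archetype: a declarative description of what may be recorded (items and
integer ranges), how items group into clinical dimensions (three
clusters: gait & balance, speech disturbance, limb coordination) and how
each element binds to a phenotype-ontology class.  Patient data enter as
:class:`ObservationRecord` instances validated against the definition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import yaml

from .errors import ConfigError, ParseError, ValidationError

ITEM_IDS = ("gait", "stance", "sitting", "speech",
            "finger_chase", "nose_finger", "alternating_hand", "heel_shin")
AXIAL_ITEMS = ITEM_IDS[:4]
BILATERAL_ITEMS = ITEM_IDS[4:]
SIDES = ("none", "right", "left")
CLUSTERS = ("gait_and_balance", "speech_disturbance", "limb_coordination")

#: column order of the observation CSV dialect
CSV_HEADER = ["patient_id", "date", "gait", "stance", "sitting", "speech",
              "finger_chase_r", "finger_chase_l", "nose_finger_r",
              "nose_finger_l", "alternating_hand_r", "alternating_hand_l",
              "heel_shin_r", "heel_shin_l"]


@dataclass(frozen=True)
class ItemDefinition:
    item_id: str
    min_score: int
    max_score: int
    bilateral: bool
    binding: str
    cluster: str

    def __post_init__(self):
        if self.item_id not in ITEM_IDS:
            raise ConfigError(f"unknown item id {self.item_id!r}")
        if not (self.min_score == 0 and self.min_score < self.max_score):
            raise ConfigError(
                f"item {self.item_id!r}: require 0 = min_score < max_score, "
                f"got [{self.min_score}, {self.max_score}]"
            )
        if self.bilateral != (self.item_id in BILATERAL_ITEMS):
            raise ConfigError(
                f"item {self.item_id!r}: bilateral must be "
                f"{self.item_id in BILATERAL_ITEMS}"
            )
        if self.cluster not in CLUSTERS:
            raise ConfigError(f"item {self.item_id!r}: unknown cluster "
                              f"{self.cluster!r}")

    @property
    def sides(self) -> tuple[str, ...]:
        return ("right", "left") if self.bilateral else ("none",)

    @property
    def score_range(self) -> range:
        return range(self.min_score, self.max_score + 1)


@dataclass(frozen=True)
class ScaleDefinition:
    """The full SARA content model (8 items, 3 clusters, max total 40)."""

    items: tuple[ItemDefinition, ...]
    cluster_bindings: dict[str, str]

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if ids != list(ITEM_IDS):
            raise ConfigError(
                f"scale must define the 8 SARA items in canonical order, "
                f"got {ids}"
            )
        if set(self.cluster_bindings) != set(CLUSTERS):
            raise ConfigError(
                f"cluster bindings must cover {CLUSTERS}, "
                f"got {sorted(self.cluster_bindings)}"
            )
        if self.max_total != 40:
            raise ConfigError(
                f"sum of item maxima (bilateral counted once) must be 40, "
                f"got {self.max_total}"
            )

    @property
    def max_total(self) -> int:
        return sum(it.max_score for it in self.items)

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def slots(self) -> list[tuple[str, str]]:
        """The 12 ``(item_id, side)`` score slots in canonical order."""
        out = []
        for it in self.items:
            out.extend((it.item_id, side) for side in it.sides)
        return out

    def resolve_bindings(self, ontology) -> None:
        """Raise if any item or cluster binding is missing from ``ontology``."""
        from .errors import UnknownClassError

        missing = [it.binding for it in self.items if it.binding not in ontology]
        missing += [c for c in self.cluster_bindings.values()
                    if c not in ontology]
        if missing:
            raise UnknownClassError(missing, context="scale bindings")


@dataclass(frozen=True)
class ObservationRecord:
    """One patient's 12 raw SARA scores on one assessment date."""

    patient_id: str
    date: str
    scores: dict[tuple[str, str], int]

    def score(self, item_id: str, side: str = "none") -> int:
        return self.scores[(item_id, side)]

    def __hash__(self):
        return hash((self.patient_id, self.date,
                     tuple(sorted(self.scores.items()))))


@dataclass(frozen=True)
class DerivedScores:
    """Bilateral side-means and the total SARA score.

    ``means`` maps each bilateral item to (right + left) / 2, always a
    multiple of 0.5; ``total`` adds the four axial scores and the four
    means, so it lies in [0, 40] on a 0.5 grid.
    """

    means: dict[str, float]
    total: float

    def __hash__(self):
        return hash((tuple(sorted(self.means.items())), self.total))


# ----------------------------------------------------------------------
# scale definition I/O
# ----------------------------------------------------------------------

def _scale_from_dict(data: dict) -> ScaleDefinition:
    try:
        items = tuple(
            ItemDefinition(
                item_id=entry["item_id"],
                min_score=int(entry["min_score"]),
                max_score=int(entry["max_score"]),
                bilateral=bool(entry["bilateral"]),
                binding=entry["binding"],
                cluster=entry["cluster"],
            )
            for entry in data["items"]
        )
        clusters = dict(data["cluster_bindings"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed scale definition: missing {exc}") from exc
    return ScaleDefinition(items=items, cluster_bindings=clusters)


def load_scale_definition(path) -> ScaleDefinition:
    """Load a scale definition from a YAML (or JSON) config file."""
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse scale config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"scale config {path} must be a mapping")
    return _scale_from_dict(data)


def default_scale() -> ScaleDefinition:
    """The packaged canonical SARA definition (gait 0-8 ... heel-shin 0-4)."""
    from importlib.resources import files

    data = yaml.safe_load(
        files("sarakit.data").joinpath("sara_scale.yaml").read_text()
    )
    return _scale_from_dict(data)


# ----------------------------------------------------------------------
# observation validation and I/O
# ----------------------------------------------------------------------

def validate_observation(scale: ScaleDefinition, raw,
                         patient_id: str = "anonymous",
                         date: str = "1970-01-01") -> ObservationRecord:
    """Validate a raw ``(item, side) -> score`` mapping against the scale.

    Every violation (missing slot, extraneous slot, non-integer value,
    out-of-range value) is collected, and a single
    :class:`~sarakit.errors.ValidationError` listing all of them is
    raised if any is found.
    """
    raw = dict(raw)
    problems: list[str] = []
    scores: dict[tuple[str, str], int] = {}
    expected = scale.slots()
    for item_id, side in expected:
        key = (item_id, side)
        if key not in raw:
            problems.append(f"missing score for ({item_id}, {side})")
            continue
        value = raw[key]
        item = scale.item(item_id)
        if isinstance(value, bool) or not isinstance(value, int):
            try:
                as_float = float(value)
            except (TypeError, ValueError):
                problems.append(
                    f"({item_id}, {side}): non-integer score {value!r}")
                continue
            if as_float != int(as_float):
                problems.append(
                    f"({item_id}, {side}): non-integer score {value!r}")
                continue
            value = int(as_float)
        if not (item.min_score <= value <= item.max_score):
            problems.append(
                f"({item_id}, {side}): score {value} outside "
                f"[{item.min_score}, {item.max_score}]"
            )
            continue
        scores[key] = value
    extras = set(raw) - set(expected)
    problems.extend(f"unexpected score slot {k}" for k in sorted(extras))
    if problems:
        raise ValidationError(
            f"invalid observation for patient {patient_id!r}", problems)
    return ObservationRecord(patient_id=patient_id, date=date, scores=scores)


def _slot_to_column(item_id: str, side: str) -> str:
    return item_id if side == "none" else f"{item_id}_{side[0]}"


def read_observations_csv(path, scale: ScaleDefinition) -> list[ObservationRecord]:
    """Read observations from the canonical CSV dialect.

    Header: ``patient_id,date,gait,...,heel_shin_l`` (see
    :data:`CSV_HEADER`).  All row-level problems are collected with their
    line numbers and raised together as one ValidationError.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header "
                             f"{','.join(CSV_HEADER)}") from None
        if [h.strip() for h in header] != CSV_HEADER:
            raise ParseError(
                f"{path}: header mismatch; expected {','.join(CSV_HEADER)}")
        records: list[ObservationRecord] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(CSV_HEADER):
                problems.append(f"line {lineno}: expected "
                                f"{len(CSV_HEADER)} columns, got {len(row)}")
                continue
            raw: dict[tuple[str, str], object] = {}
            row_problems = []
            for (item_id, side), cell in zip(
                    [(i, s) for i, s in scale.slots()], row[2:]):
                column = _slot_to_column(item_id, side)
                try:
                    raw[(item_id, side)] = int(cell)
                except ValueError:
                    row_problems.append(
                        f"line {lineno}, column {column}: "
                        f"non-integer value {cell!r}")
            if row_problems:
                problems.extend(row_problems)
                continue
            try:
                records.append(validate_observation(
                    scale, raw, patient_id=row[0].strip(), date=row[1].strip()))
            except ValidationError as exc:
                problems.extend(f"line {lineno}: {d}" for d in exc.details)
    if problems:
        raise ValidationError(f"invalid observation rows in {path}", problems)
    return records


def write_observations_csv(records, path) -> None:
    """Write observations in the dialect read by :func:`read_observations_csv`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            row = [rec.patient_id, rec.date]
            for column in CSV_HEADER[2:]:
                if column.endswith(("_r", "_l")):
                    item_id, side = column[:-2], \
                        {"r": "right", "l": "left"}[column[-1]]
                else:
                    item_id, side = column, "none"
                row.append(rec.scores[(item_id, side)])
            writer.writerow(row)


def observation_to_xml(record: ObservationRecord) -> str:
    """Deterministic XML rendering of one observation (data-exchange payload)."""
    root = ET.Element("observation", patient_id=record.patient_id,
                      date=record.date)
    for (item_id, side) in sorted(record.scores):
        ET.SubElement(root, "score", item=item_id, side=side,
                      value=str(record.scores[(item_id, side)]))
    return ET.tostring(root, encoding="unicode")


def observation_from_xml(text: str) -> ObservationRecord:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"bad observation XML: {exc}") from exc
    scores = {
        (el.get("item"), el.get("side")): int(el.get("value"))
        for el in root.findall("score")
    }
    return ObservationRecord(patient_id=root.get("patient_id"),
                             date=root.get("date"), scores=scores)
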