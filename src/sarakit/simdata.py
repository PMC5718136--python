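"""Fixtures and synthetic data: the SARA phenotype slim, archetypal
patients, and noisy-rater simulation.

Real expert ratings and patient cohorts are not distributable, so this
module generates everything the rest of the package (and its tests)
consumes:

* :func:`sara_ontology` builds the SARA phenotype slim programmatically
  (the packaged OBO file is its serialization);
* :func:`table1_patients` returns three archetypal patients sharing a
  total SARA score of 20 with very different phenotypes (midline-
  dominant; symmetric appendicular + mild dysarthria; asymmetric
  appendicular + anarthria);
* :func:`generate_profile` draws random observations whose total lands
  in a requested syndrome band, loaded according to a clinical
  archetype;
* :func:`simulate_raters` produces paired ordinal ratings with a
  controlled agreement probability for exercising the kappa harness.

All randomness flows through one seeded NumPy generator per call; no
global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleBandError, ValidationError
from .ontology import OntologyClass, PhenotypeOntology, SEVERITY_LEVELS
from .scale import (
    AXIAL_ITEMS,
    BILATERAL_ITEMS,
    ObservationRecord,
    ScaleDefinition,
    validate_observation,
)

ARCHETYPES = ("none", "midline_dominant", "appendicular_symmetric",
              "appendicular_asymmetric", "mixed")
BANDS = ("absent", "mild", "moderate", "severe", "very severe")
_BAND_RANGES = {"absent": (0.0, 1.0), "mild": (1.0, 10.0),
                "moderate": (10.0, 20.0), "severe": (20.0, 30.0),
                "very severe": (30.0, 40.0)}


# ----------------------------------------------------------------------
# the SARA phenotype slim
# ----------------------------------------------------------------------

_LIMB_CLASSES = ("limb_dysmetria", "lower_limb_dysmetria",
                 "intention_tremor", "dysdiadochokinesis")
_GRADED_CLASSES = ("gait_ataxia", "standing_instability",
                   "sitting_instability", "dysarthria") + _LIMB_CLASSES


def sara_ontology() -> PhenotypeOntology:
    """Build the SARA phenotype slim (109 abnormality subclasses).

    The skeleton: truncal (midline) ataxia subsumes gait ataxia and
    ataxic postural instability (itself subsuming standing and sitting
    instability); appendicular ataxia subsumes limb dysmetria, intention
    tremor and dysdiadochokinesis; abasia, astasia and anarthria are the
    terminal classes anchored to the maximal gait/stance/speech scores.
    Each graded class carries five severity subclasses, the four limb
    classes additionally carry left/right variants with their own
    severity subclasses (multi-parented under both the side variant and
    the plain severity subclass), and the cerebellar-syndrome class
    carries five severity subclasses for the global assessment.
    """
    def cls(cid, label, *parents, severity=None, laterality=None):
        return OntologyClass(id=cid, label=label,
                             parents=frozenset(parents), severity=severity,
                             laterality=laterality)

    classes = [
        cls("phenotypic_abnormality", "Phenotypic abnormality"),
        cls("ataxia", "Ataxia", "phenotypic_abnormality"),
        cls("truncal_ataxia", "Truncal ataxia", "ataxia"),
        cls("gait_ataxia", "Gait ataxia", "truncal_ataxia"),
        cls("abasia", "Abasia", "gait_ataxia"),
        cls("ataxic_postural_instability", "Ataxic postural instability",
            "truncal_ataxia"),
        cls("standing_instability", "Standing instability",
            "ataxic_postural_instability"),
        cls("astasia", "Astasia", "standing_instability"),
        cls("sitting_instability", "Sitting instability",
            "ataxic_postural_instability"),
        cls("dysarthria", "Dysarthria", "phenotypic_abnormality"),
        cls("anarthria", "Anarthria", "dysarthria"),
        cls("appendicular_ataxia", "Appendicular ataxia", "ataxia"),
        cls("limb_dysmetria", "Limb dysmetria", "appendicular_ataxia"),
        cls("lower_limb_dysmetria", "Lower limb dysmetria", "limb_dysmetria"),
        cls("intention_tremor", "Intention tremor", "appendicular_ataxia"),
        cls("dysdiadochokinesis", "Dysdiadochokinesis",
            "appendicular_ataxia"),
        cls("cerebellar_syndrome", "Cerebellar syndrome",
            "phenotypic_abnormality"),
    ]
    ont = PhenotypeOntology(classes, root="phenotypic_abnormality")

    # severity subclasses of every graded class and of the syndrome
    for base in _GRADED_CLASSES + ("cerebellar_syndrome",):
        ont = ont.add_severity_subclasses(base, SEVERITY_LEVELS)

    # left/right variants of the limb classes, each with severity
    # subclasses that are also subclasses of the plain severity class
    side_classes = []
    for base in _LIMB_CLASSES:
        for side in ("left", "right"):
            sid = f"{side}_{base}"
            label = ont[base].label
            side_classes.append(cls(sid, f"{label} ({side})", base,
                                    laterality=side))
    ont = PhenotypeOntology(list(ont.classes.values()) + side_classes,
                            root="phenotypic_abnormality")
    lateral_severity = []
    for base in _LIMB_CLASSES:
        for side in ("left", "right"):
            for level in SEVERITY_LEVELS:
                lateral_severity.append(cls(
                    f"{level}_{side}_{base}",
                    f"{level.capitalize()} {ont[base].label.lower()} ({side})",
                    f"{side}_{base}", f"{level}_{base}",
                    severity=level, laterality=side,
                ))
    return PhenotypeOntology(
        list(ont.classes.values()) + lateral_severity,
        root="phenotypic_abnormality",
    )


def toy_ontology() -> PhenotypeOntology:
    """Tiny 6-class ontology (root <- {A <- {A1, A2}, B <- B1})."""
    def cls(cid, *parents):
        return OntologyClass(id=cid, label=cid.upper(),
                             parents=frozenset(parents))

    return PhenotypeOntology(
        [cls("root"), cls("A", "root"), cls("A1", "A"), cls("A2", "A"),
         cls("B", "root"), cls("B1", "B")],
        root="root",
    )


def random_dag_ontology(n_classes: int, seed: int,
                        extra_edge_prob: float = 0.15) -> PhenotypeOntology:
    """Random rooted DAG ontology for property tests.

    Node ``i`` gets one guaranteed parent among ``0..i-1`` (so the DAG is
    rooted and connected) plus extra earlier parents with probability
    ``extra_edge_prob`` each — edges always point from later to earlier
    indices, hence acyclicity by construction.
    """
    rng = np.random.default_rng(seed)
    classes = [OntologyClass(id="c0", label="c0")]
    for i in range(1, n_classes):
        parents = {f"c{rng.integers(0, i)}"}
        for j in range(i):
            if rng.random() < extra_edge_prob:
                parents.add(f"c{j}")
        classes.append(OntologyClass(id=f"c{i}", label=f"c{i}",
                                     parents=frozenset(parents)))
    return PhenotypeOntology(classes, root="c0")


# ----------------------------------------------------------------------
# archetypal patients
# ----------------------------------------------------------------------

def _record(patient_id, axial, bilateral, date="2016-01-01"):
    scores = dict(zip(((i, "none") for i in AXIAL_ITEMS), axial))
    for item, (r, l) in zip(BILATERAL_ITEMS, bilateral):
        scores[(item, "right")] = r
        scores[(item, "left")] = l
    return ObservationRecord(patient_id=patient_id, date=date, scores=scores)


def table1_patients() -> list[ObservationRecord]:
    """The three archetypal patients, all with total SARA score 20.

    Patient 1 is midline-dominant (can barely walk, stand or sit
    unaided), patient 2 has symmetric limb incoordination with mild
    dysarthria, and patient 3 combines anarthria with a strongly
    left-lateralized limb syndrome.
    """
    return [
        _record("patient-1", (6, 6, 3, 1),
                ((0, 0), (1, 1), (1, 1), (2, 2))),
        _record("patient-2", (2, 2, 1, 3),
                ((3, 4), (3, 4), (3, 3), (2, 2))),
        _record("patient-3", (2, 2, 1, 6),
                ((1, 4), (1, 4), (1, 4), (0, 3))),
    ]


# ----------------------------------------------------------------------
# random profile generation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSpec:
    """How to draw one synthetic patient."""

    archetype: str = "none"
    severity_target: str = "moderate"  # syndrome band the total must hit
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.severity_target not in BANDS:
            raise ValidationError(f"unknown band {self.severity_target!r}")


def _archetype_caps(scale: ScaleDefinition, archetype: str):
    """Per-slot score caps expressing an archetype's clinical loading."""
    caps = {slot: scale.item(slot[0]).max_score for slot in scale.slots()}
    if archetype == "midline_dominant":
        for item in BILATERAL_ITEMS:
            caps[(item, "right")] = caps[(item, "left")] = 0
    elif archetype in ("appendicular_symmetric", "appendicular_asymmetric"):
        for item in AXIAL_ITEMS:
            caps[(item, "none")] = 0
    elif archetype == "mixed":
        # speech + limbs carry the load; trunk involvement stays light
        for item in ("gait", "stance", "sitting"):
            caps[(item, "none")] = min(2, caps[(item, "none")])
    return caps


def _bounded_composition(rng, total: int, slots, caps) -> dict:
    """Uniform-ish random partition of ``total`` over ``slots`` with caps.

    Visits slots in random order; each draw is taken from the exact
    feasible range given the remaining capacity, so the partition always
    lands on ``total``.
    """
    out = {slot: 0 for slot in slots}
    remaining = total
    caps_left = sum(caps[s] for s in slots)
    for idx in rng.permutation(len(slots)):
        slot = slots[int(idx)]
        caps_left -= caps[slot]
        lo = max(0, remaining - caps_left)
        hi = min(caps[slot], remaining)
        value = int(rng.integers(lo, hi + 1))
        out[slot] = value
        remaining -= value
    assert remaining == 0
    return out


def generate_profile(scale: ScaleDefinition,
                     spec: ProfileSpec) -> ObservationRecord:
    """Draw one observation whose total falls in the requested band.

    The total T is picked uniformly from the band's reachable 0.5-grid
    under the archetype's per-slot caps, then split into an axial-score
    sum A and a lateral-score sum L = 2(T - A), and each sum is randomly
    partitioned over its slots.  For the asymmetric archetype the off
    side's limb-score sum is kept strictly below the loaded side's.
    Identical specs yield identical records.
    """
    rng = np.random.default_rng(spec.seed)
    caps = _archetype_caps(scale, spec.archetype)
    asymmetric = spec.archetype == "appendicular_asymmetric"

    axial_slots = [(i, "none") for i in AXIAL_ITEMS]
    lateral_slots = [(i, s) for i in BILATERAL_ITEMS
                     for s in ("right", "left")]
    acap = sum(caps[s] for s in axial_slots)
    lcap = sum(caps[s] for s in lateral_slots)
    side_cap = lcap // 2
    if asymmetric:
        lcap -= 1  # off side stays strictly below the loaded side

    lo, hi = _BAND_RANGES[spec.severity_target]
    max_total = acap + lcap / 2.0
    step = 0.5 if lcap > 0 else 1.0
    grid = np.arange(0.0, max_total + 1e-9, step)
    if spec.severity_target == "absent":
        # absent means no findings: all-zero record (the asymmetric
        # archetype needs one point on the loaded side to stay asymmetric)
        candidates = np.array([0.5 if asymmetric else 0.0])
    else:
        candidates = grid[(grid > lo) & (grid <= hi)]
    if candidates.size == 0:
        raise InfeasibleBandError(
            f"archetype {spec.archetype!r} cannot reach band "
            f"{spec.severity_target!r} (max reachable total {max_total:g})")
    total = float(rng.choice(candidates))

    # split T into axial points A and lateral units L = 2(T - A)
    a_lo = max(0, int(np.ceil(total - lcap / 2.0 - 1e-9)))
    a_hi = min(acap, int(np.floor(total + 1e-9)))
    axial_sum = int(rng.integers(a_lo, a_hi + 1))
    lateral_sum = round(2 * (total - axial_sum))

    scores = _bounded_composition(rng, axial_sum, axial_slots, caps)
    if asymmetric:
        loaded = "left" if rng.random() < 0.5 else "right"
        off = "right" if loaded == "left" else "left"
        # loaded-side sum S must satisfy L - S <= S - 1 and both side caps
        s_lo = max((lateral_sum + 1 + 1) // 2, lateral_sum - side_cap)
        s_hi = min(side_cap, lateral_sum)
        loaded_sum = int(rng.integers(s_lo, s_hi + 1))
        for side, side_total in ((loaded, loaded_sum),
                                 (off, lateral_sum - loaded_sum)):
            side_slots = [(i, side) for i in BILATERAL_ITEMS]
            scores.update(_bounded_composition(rng, side_total, side_slots,
                                               caps))
    else:
        scores.update(_bounded_composition(rng, lateral_sum, lateral_slots,
                                           caps))

    return validate_observation(
        scale, scores,
        patient_id=f"sim-{spec.archetype}-{spec.seed}",
        date="2016-01-01")


# ----------------------------------------------------------------------
# noisy-rater simulation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RaterSpec:
    """Noisy ordinal rater: reports the truth with ``agreement_prob``,
    otherwise a different label at most ``drift`` ordinal steps away."""

    agreement_prob: float
    drift: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.agreement_prob <= 1.0:
            raise ValidationError("agreement_prob must be in [0, 1]")
        if self.drift < 1:
            raise ValidationError("drift must be >= 1")


def simulate_raters(truth, spec: RaterSpec, categories=None):
    """Two independent noisy raters observing the same ordinal truth.

    Each rater reports the true label with probability
    ``spec.agreement_prob`` and otherwise a label drawn uniformly from
    the other categories within ``spec.drift`` ordinal steps.  Returns
    ``(rater_a, rater_b)`` lists; reproducible from ``spec.seed``.
    """
    truth = list(truth)
    if not truth:
        raise ValidationError("truth list must be non-empty")
    if categories is None:
        categories = sorted(set(truth))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    unknown = [t for t in truth if t not in index]
    if unknown:
        raise ValidationError(f"truth label(s) not in categories: "
                              f"{sorted(set(map(str, unknown)))}")
    rng = np.random.default_rng(spec.seed)

    def rate_all():
        out = []
        for t in truth:
            i = index[t]
            if rng.random() < spec.agreement_prob:
                out.append(t)
                continue
            neighbors = [j for j in range(len(categories))
                         if j != i and abs(j - i) <= spec.drift]
            if not neighbors:
                out.append(t)
                continue
            out.append(categories[neighbors[rng.integers(len(neighbors))]])
        return out

    return rate_all(), rate_all()


def uniform_truth(categories, n: int, seed: int) -> list:
    """Uniformly random ordinal truth sequence (for kappa calibration)."""
    rng = np.random.default_rng(seed)
    categories = list(categories)
    return [categories[i] for i in rng.integers(len(categories), size=n)]
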