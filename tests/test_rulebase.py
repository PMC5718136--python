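"""Rule-base construction, stage execution and the interpretation pipeline."""

from __future__ import annotations

import dataclasses
import random

import pytest

from sarakit.errors import ConfigError
from sarakit.rulebase import (
    DEFAULT_SYNDROME_BANDS,
    RuleBase,
    apply_assessment_rules,
    apply_calculation_rules,
    apply_severity_rules,
    build_sara_rulebase,
    run_pipeline,
)
from sarakit.scale import DerivedScores, validate_observation
from sarakit.synopsis import severity_rank


def _obs(scale, **overrides):
    """All-zero observation with per-slot overrides like gait=3 or
    finger_chase_right=4."""
    raw = {slot: 0 for slot in scale.slots()}
    for key, value in overrides.items():
        if key.endswith(("_right", "_left")):
            item, side = key.rsplit("_", 1)
        else:
            item, side = key, "none"
        raw[(item, side)] = value
    return validate_observation(scale, raw, patient_id="t")


def _finding_for(scale, rb, element, **overrides):
    obs = _obs(scale, **overrides)
    derived = apply_calculation_rules(rb, obs)
    findings = apply_severity_rules(rb, obs, derived)
    return next(f for f in findings if f.element == element)


class TestStructure:
    def test_exactly_five_calculation_rules(self, rb):
        assert len(rb.calculation_rules) == 5

    def test_every_score_matches_exactly_one_severity_rule(self, scale, rb):
        """Cut-off intervals are disjoint and exhaustive per item and side."""
        for item in scale.items:
            for side in item.sides:
                element = (item.item_id if side == "none"
                           else f"{item.item_id}.{side}")
                rules = [r for r in rb.severity_rules
                         if r.action.element == element]
                for score in item.score_range:
                    matched = [r for r in rules
                               if r.matches({element: score})]
                    assert len(matched) == 1, (element, score)

    def test_overlapping_override_rejected(self, scale):
        with pytest.raises(ConfigError, match="overlap"):
            build_sara_rulebase(scale, cutoff_overrides={"sitting": [
                {"min": 0, "max": 2, "severity": "mild"},
                {"min": 2, "max": 4, "severity": "severe"},
            ]})

    def test_uncovered_override_rejected(self, scale):
        with pytest.raises(ConfigError, match="uncovered"):
            build_sara_rulebase(scale, cutoff_overrides={"sitting": [
                {"min": 0, "max": 2, "severity": "mild"},
                {"min": 4, "max": 4, "severity": "severe"},
            ]})

    def test_per_score_drop_in_table_changes_rule_count(self, scale, rb):
        """A full per-score cut-off table can replace the default bins."""
        per_score = {}
        for item in scale.items:
            per_score[item.item_id] = [
                {"min": s, "max": s,
                 "severity": "absent" if s == 0 else "moderate"}
                for s in item.score_range
            ]
        custom = build_sara_rulebase(scale, cutoff_overrides=per_score)
        expected = sum(len(item.score_range) * len(item.sides)
                       for item in scale.items)
        assert len(custom.severity_rules) == expected
        assert len(custom.severity_rules) != len(rb.severity_rules)

    def test_bad_band_config_rejected(self, scale):
        with pytest.raises(ConfigError, match="contiguous"):
            build_sara_rulebase(scale, syndrome_bands=[
                {"category": "absent", "max": 1},
                {"category": "moderate", "min": 5, "max": 40},
            ])

    def test_serialization_round_trip(self, rb, tmp_path):
        path = tmp_path / "rules.yaml"
        rb.save(path)
        assert RuleBase.load(path) == rb


class TestCalculation:
    def test_table1_means_and_totals(self, scale, rb, table1):
        expected_means = [
            {"finger_chase": 0.0, "nose_finger": 1.0,
             "alternating_hand": 1.0, "heel_shin": 2.0},
            {"finger_chase": 3.5, "nose_finger": 3.5,
             "alternating_hand": 3.0, "heel_shin": 2.0},
            {"finger_chase": 2.5, "nose_finger": 2.5,
             "alternating_hand": 2.5, "heel_shin": 1.5},
        ]
        for obs, means in zip(table1, expected_means):
            derived = apply_calculation_rules(rb, obs)
            assert derived.means == means
            assert derived.total == 20.0

    def test_all_zero(self, scale, rb):
        derived = apply_calculation_rules(rb, _obs(scale))
        assert derived.total == 0.0
        assert set(derived.means.values()) == {0.0}

    def test_total_monotone_in_every_single_score(self, scale, rb):
        """Raising any one raw score never lowers the total."""
        rng = random.Random(4)
        for _ in range(20):
            raw = {slot: rng.randint(0, scale.item(slot[0]).max_score)
                   for slot in scale.slots()}
            base = validate_observation(scale, raw)
            base_total = apply_calculation_rules(rb, base).total
            for slot in scale.slots():
                if raw[slot] >= scale.item(slot[0]).max_score:
                    continue
                bumped = dict(raw)
                bumped[slot] += 1
                total = apply_calculation_rules(
                    rb, validate_observation(scale, bumped)).total
                assert total >= base_total

    def test_total_on_half_grid(self, scale, rb):
        rng = random.Random(5)
        for _ in range(50):
            raw = {slot: rng.randint(0, scale.item(slot[0]).max_score)
                   for slot in scale.slots()}
            total = apply_calculation_rules(
                rb, validate_observation(scale, raw)).total
            assert 0.0 <= total <= 40.0
            assert (2 * total) == int(2 * total)


class TestSeverity:
    def test_sitting_4_is_severe_sitting_instability(self, scale, rb):
        f = _finding_for(scale, rb, "sitting", sitting=4)
        assert (f.onto_class, f.severity) == ("sitting_instability", "severe")

    def test_gait_8_is_abasia(self, scale, rb):
        f = _finding_for(scale, rb, "gait", gait=8)
        assert f.onto_class == "abasia" and f.severity is None

    def test_speech_6_is_anarthria(self, scale, rb):
        f = _finding_for(scale, rb, "speech", speech=6)
        assert f.onto_class == "anarthria"

    def test_stance_6_is_astasia(self, scale, rb):
        f = _finding_for(scale, rb, "stance", stance=6)
        assert f.onto_class == "astasia"

    def test_gait_3_is_moderate_gait_ataxia(self, scale, rb):
        f = _finding_for(scale, rb, "gait", gait=3)
        assert (f.onto_class, f.severity) == ("gait_ataxia", "moderate")

    def test_score_zero_yields_explicit_absent_finding(self, scale, rb):
        f = _finding_for(scale, rb, "gait")
        assert f.absent and f.onto_class == "gait_ataxia"

    def test_bilateral_findings_carry_laterality(self, scale, rb):
        f = _finding_for(scale, rb, "finger_chase.left",
                         finger_chase_left=4)
        assert (f.onto_class, f.severity, f.laterality) == \
            ("limb_dysmetria", "severe", "left")

    def test_severity_monotone_per_item(self, scale, rb):
        """Higher raw score never maps to a lower severity rank."""
        for item in scale.items:
            for side in item.sides:
                element = (item.item_id if side == "none"
                           else f"{item.item_id}.{side}")
                key = (item.item_id if side == "none"
                       else f"{item.item_id}_{side}")
                ranks = [
                    severity_rank(_finding_for(
                        scale, rb, element, **{key: s}).severity)
                    for s in item.score_range
                ]
                assert ranks == sorted(ranks), element


class TestAssessment:
    @pytest.mark.parametrize("total,category", [
        (0.0, "absent"), (0.5, "absent"), (1.0, "absent"),
        (1.5, "mild"), (10.0, "mild"), (10.5, "moderate"),
        (20.0, "moderate"), (20.5, "severe"), (30.0, "severe"),
        (30.5, "very severe"), (40.0, "very severe"),
    ])
    def test_default_banding(self, rb, total, category):
        derived = DerivedScores(means={}, total=total)
        assert apply_assessment_rules(rb, derived).category == category

    def test_every_half_step_matches_one_band(self, rb):
        for twice in range(0, 81):
            derived = DerivedScores(means={}, total=twice / 2)
            apply_assessment_rules(rb, derived)  # must not raise

    def test_default_bands_partition_0_40(self):
        highs = [b.get("max") for b in DEFAULT_SYNDROME_BANDS[:-1]]
        lows = [b.get("min") for b in DEFAULT_SYNDROME_BANDS[1:]]
        assert highs == lows


class TestPipeline:
    def test_patient1_gait_and_balance_is_severe(self, scale, rb, sara_ont,
                                                 table1):
        record = run_pipeline(scale, rb, sara_ont, table1[0])
        cluster = record.findings["gait_and_balance"]
        assert max(f.rank for f in cluster) >= severity_rank("severe")
        assert record.assessment.category == "moderate"

    def test_patient3_lateralized_findings(self, scale, rb, sara_ont, table1):
        record = run_pipeline(scale, rb, sara_ont, table1[2])
        limb = record.findings["limb_coordination"]
        right = max(f.rank for f in limb if f.laterality == "right")
        left = max(f.rank for f in limb if f.laterality == "left")
        assert right == severity_rank("mild")
        assert left == severity_rank("severe")

    def test_all_zero_observation(self, scale, rb, sara_ont):
        record = run_pipeline(scale, rb, sara_ont, _obs(scale))
        assert record.assessment.category == "absent"
        assert all(f.absent for fs in record.findings.values() for f in fs)
        assert record.inferred == frozenset()
        assert not any(f.present for f in record.synopsis.features)

    def test_stage_order_permutation_invariance(self, scale, rb, sara_ont,
                                                table1):
        """Rules within a stage are condition-disjoint, so shuffling them
        does not change the pipeline output (trace order aside)."""
        rng = random.Random(11)
        shuffled = list(rb.rules)
        # shuffle within each stage, keep stage blocks intact
        by_stage = {}
        for r in shuffled:
            by_stage.setdefault(r.stage, []).append(r)
        for rules in by_stage.values():
            rng.shuffle(rules)
        rb2 = RuleBase(name=rb.name, version=rb.version, rules=tuple(
            by_stage["calculation"] + by_stage["severity"]
            + by_stage["assessment"]))
        for obs in table1:
            a = run_pipeline(scale, rb, sara_ont, obs)
            b = run_pipeline(scale, rb2, sara_ont, obs)
            assert dataclasses.replace(a, trace=()) == \
                dataclasses.replace(b, trace=())
            assert sorted(a.trace) == sorted(b.trace)

    def test_pipeline_deterministic(self, scale, rb, sara_ont, table1):
        a = run_pipeline(scale, rb, sara_ont, table1[1])
        b = run_pipeline(scale, rb, sara_ont, table1[1])
        assert a == b and a.report == b.report
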