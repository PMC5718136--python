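"""Ontology loading, validation, reasoning and module extraction."""

from __future__ import annotations

import numpy as np
import pytest
from conftest import bfs_ancestors, parent_map_of

from sarakit.errors import (
    DuplicateClassError,
    UnknownClassError,
    ValidationError,
)
from sarakit.ontology import (
    OntologyClass,
    OwlImportWarning,
    PhenotypeOntology,
    import_owl_subclass_hierarchy,
    load_obo,
    write_obo,
    write_owl,
)
from sarakit.simdata import random_dag_ontology, sara_ontology


def _obo(tmp_path, text):
    path = tmp_path / "t.obo"
    path.write_text("format-version: 1.2\n\n" + text)
    return path


class TestLoadObo:
    def test_three_term_chain(self, tmp_path):
        path = _obo(tmp_path, (
            "[Term]\nid: root\nname: Root\n\n"
            "[Term]\nid: A\nname: A\nis_a: root\n\n"
            "[Term]\nid: B\nname: B\nis_a: A\n"
        ))
        ont = load_obo(path)
        assert len(ont) == 3
        assert ont.ancestors("B") == {"A", "root"}

    def test_cycle_names_offending_classes(self, tmp_path):
        path = _obo(tmp_path, (
            "[Term]\nid: root\nname: Root\n\n"
            "[Term]\nid: A\nname: A\nis_a: root\nis_a: B\n\n"
            "[Term]\nid: B\nname: B\nis_a: A\n"
        ))
        with pytest.raises(ValidationError, match="cycle") as exc:
            load_obo(path, root="root")
        assert "A" in str(exc.value) and "B" in str(exc.value)

    def test_dangling_parent_reported(self, tmp_path):
        path = _obo(tmp_path, (
            "[Term]\nid: root\nname: Root\n\n"
            "[Term]\nid: A\nname: A\nis_a: ghost\n"
        ))
        with pytest.raises(ValidationError, match="ghost"):
            load_obo(path, root="root")

    def test_obsolete_terms_dropped(self, tmp_path):
        path = _obo(tmp_path, (
            "[Term]\nid: root\nname: Root\n\n"
            "[Term]\nid: A\nname: A\nis_a: root\n\n"
            "[Term]\nid: old\nname: Old\nis_a: root\nis_obsolete: true\n"
        ))
        assert set(load_obo(path).classes) == {"root", "A"}

    def test_severity_qualifier_round_trip(self, tmp_path):
        path = _obo(tmp_path, (
            "[Term]\nid: root\nname: Root\n\n"
            "[Term]\nid: mild_x\nname: Mild X\nis_a: root\n"
            'property_value: has_severity "mild" xsd:string\n'
        ))
        assert load_obo(path)["mild_x"].severity == "mild"


class TestSaraSlim:
    """The packaged scaled-down phenotype ontology."""

    def test_has_109_abnormality_subclasses(self, sara_ont):
        assert sara_ont.subclass_count("phenotypic_abnormality") == 109

    def test_matches_programmatic_builder(self, sara_ont):
        assert sara_ont == sara_ontology()

    def test_abasia_is_a_gait_and_truncal_ataxia(self, sara_ont):
        assert {"gait_ataxia", "truncal_ataxia"} <= sara_ont.ancestors("abasia")

    def test_severity_subclass_structure(self, sara_ont):
        cls = sara_ont["moderate_dysarthria"]
        assert cls.parents == frozenset({"dysarthria"})
        assert cls.severity == "moderate"

    def test_root_has_no_ancestors(self, sara_ont):
        assert sara_ont.ancestors(sara_ont.root) == set()

    def test_obo_round_trip(self, sara_ont, tmp_path):
        path = tmp_path / "slim.obo"
        write_obo(sara_ont, path)
        assert load_obo(path, root=sara_ont.root) == sara_ont


class TestReasoning:
    @pytest.mark.parametrize("seed,n", [(0, 50), (1, 50), (2, 120), (3, 200)])
    def test_ancestors_equal_bfs_reachability(self, seed, n):
        ont = random_dag_ontology(n, seed)
        parents = parent_map_of(ont)
        for cid in ont.classes:
            assert ont.ancestors(cid) == bfs_ancestors(parents, cid)

    def test_ancestors_unknown_class(self, toy_ont):
        with pytest.raises(UnknownClassError):
            toy_ont.ancestors("nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_classify_individual_equals_union_of_closures(self, seed):
        ont = random_dag_ontology(60, seed)
        parents = parent_map_of(ont)
        rng = np.random.default_rng(seed)
        ids = sorted(ont.classes)
        asserted = {ids[i] for i in rng.integers(0, len(ids), size=6)}
        expected = set(asserted)
        for a in asserted:
            expected |= bfs_ancestors(parents, a)
        assert ont.classify_individual(asserted) == expected

    def test_classify_individual_monotone(self):
        ont = random_dag_ontology(60, 7)
        ids = sorted(ont.classes)
        small = set(ids[5:10])
        large = small | set(ids[20:30])
        assert ont.classify_individual(small) <= ont.classify_individual(large)

    def test_classify_example_truncal_subsumption(self, sara_ont):
        inferred = sara_ont.classify_individual(
            {"standing_instability", "sitting_instability"})
        assert {"ataxic_postural_instability", "truncal_ataxia"} <= inferred

    def test_classify_empty(self, sara_ont):
        assert sara_ont.classify_individual(set()) == set()


class TestAcyclicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_dags_accepted(self, seed):
        assert len(random_dag_ontology(40, seed)) == 40

    @pytest.mark.parametrize("seed", range(5))
    def test_cycles_rejected(self, seed):
        ont = random_dag_ontology(40, seed)
        classes = list(ont.classes.values())
        # redirect the root's parents onto a random non-root node: the
        # chain node -> ... -> root -> node closes a directed cycle
        rng = np.random.default_rng(seed)
        other = f"c{rng.integers(1, 40)}"
        classes = [
            OntologyClass(id="c0", label="c0", parents=frozenset({other}))
            if c.id == "c0" else c
            for c in classes
        ]
        with pytest.raises(ValidationError, match="cycle"):
            PhenotypeOntology(classes, root="c0")


class TestExtractModule:
    def test_seed_is_root(self, toy_ont):
        module = toy_ont.extract_module({"root"})
        assert set(module.classes) == {"root"}

    def test_hand_enumerated_closure(self, toy_ont):
        module = toy_ont.extract_module({"A1"})
        assert set(module.classes) == {"root", "A", "A1"}

    def test_all_leaves_covers_whole_toy(self, toy_ont):
        module = toy_ont.extract_module({"A1", "A2", "B1"})
        assert set(module.classes) == set(toy_ont.classes)

    @pytest.mark.parametrize("seed", range(4))
    def test_module_is_upward_closed_and_idempotent(self, seed):
        ont = random_dag_ontology(60, seed)
        ids = sorted(ont.classes)
        seeds = set(ids[10:16])
        module = ont.extract_module(seeds)
        # upward closure: every parent of a retained class is retained
        for cls in module.classes.values():
            assert cls.parents <= set(module.classes)
        again = module.extract_module(seeds)
        assert set(again.classes) == set(module.classes)
        # equals brute-force union of per-seed closures (plus seeds/root)
        parents = parent_map_of(ont)
        expected = set(seeds) | {"c0"}
        for s in seeds:
            expected |= bfs_ancestors(parents, s)
        assert set(module.classes) == expected

    def test_unknown_seed_listed(self, toy_ont):
        with pytest.raises(UnknownClassError, match="ghost"):
            toy_ont.extract_module({"A1", "ghost"})


class TestSeveritySubclasses:
    def test_generated_subclass(self, toy_ont):
        ont = toy_ont.add_severity_subclasses("A", ["moderate"])
        cls = ont["moderate_A"]
        assert cls.parents == frozenset({"A"})
        assert cls.severity == "moderate"

    def test_empty_levels_is_identity(self, toy_ont):
        assert toy_ont.add_severity_subclasses("A", []) == toy_ont

    def test_all_levels_inherit_ancestors(self, toy_ont):
        ont = toy_ont.add_severity_subclasses(
            "A1", ["borderline", "mild", "moderate", "severe", "profound"])
        base_anc = ont.ancestors("A1")
        for level in ("borderline", "mild", "moderate", "severe", "profound"):
            assert ont.ancestors(f"{level}_A1") >= base_anc | {"A1"}

    def test_duplicate_id_rejected(self, sara_ont):
        with pytest.raises(DuplicateClassError):
            sara_ont.add_severity_subclasses("dysarthria", ["moderate"])


_OWL_MINIMAL = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Class rdf:about="http://x/pheno#root">
    <rdfs:label>Root</rdfs:label>
  </owl:Class>
  <owl:Class rdf:about="http://x/pheno#child">
    <rdfs:subClassOf rdf:resource="http://x/pheno#root"/>
  </owl:Class>
</rdf:RDF>
"""

_OWL_RESTRICTION = _OWL_MINIMAL.replace(
    "</rdf:RDF>",
    """<owl:Class rdf:about="http://x/pheno#child">
    <rdfs:subClassOf>
      <owl:Restriction>
        <owl:onProperty rdf:resource="http://x/pheno#has_severity"/>
      </owl:Restriction>
    </rdfs:subClassOf>
  </owl:Class>
</rdf:RDF>""",
)


class TestOwlImport:
    def test_minimal_two_class_import(self, tmp_path):
        path = tmp_path / "min.owl"
        path.write_text(_OWL_MINIMAL)
        ont = import_owl_subclass_hierarchy(path)
        assert set(ont.classes) == {"root", "child"}
        assert ont["child"].parents == frozenset({"root"})
        assert ont["root"].label == "Root"

    def test_restriction_axiom_skipped_with_warning(self, tmp_path):
        path = tmp_path / "res.owl"
        path.write_text(_OWL_RESTRICTION)
        with pytest.warns(OwlImportWarning, match="1 non-named"):
            ont = import_owl_subclass_hierarchy(path)
        plain = tmp_path / "min.owl"
        plain.write_text(_OWL_MINIMAL)
        assert ont.classes == import_owl_subclass_hierarchy(plain).classes

    def test_owl_round_trip_preserves_subclass_counts(self, sara_ont, tmp_path):
        path = tmp_path / "slim.owl"
        write_owl(sara_ont, path)
        imported = import_owl_subclass_hierarchy(
            path, root="phenotypic_abnormality")
        assert imported.subclass_count("phenotypic_abnormality") == 109
        assert {c: set(v.parents) for c, v in imported.classes.items()} == \
            {c: set(v.parents) for c, v in sara_ont.classes.items()}


class TestExports:
    def test_node_link_and_dot(self, toy_ont):
        data = toy_ont.to_node_link()
        assert {n["id"] for n in data["nodes"]} == set(toy_ont.classes)
        assert len(data["links"]) == 5
        dot = toy_ont.to_dot(restrict={"root", "A", "A1"})
        assert '"A1" -> "A"' in dot and '"B"' not in dot
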