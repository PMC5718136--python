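"""A small phenotype ontology: an acyclic ``is_a`` hierarchy of named classes.

The ontology used throughout sarakit is a scaled-down module of a large
phenotype terminology (in the style of an HPO slim): a rooted DAG of
phenotypic-abnormality classes, each optionally qualified by a severity
level (borderline .. profound) and a laterality.  All reasoning the SARA
interpretation pipeline needs is named-class subsumption — transitive
closure over ``is_a`` — so that is what this module implements, plus the
editing operations used to build the SARA slim: seed-based module
extraction and severity-subclass generation.

Serialization is an OBO 1.4 flat-file subset (``id`` / ``name`` / ``is_a``
/ ``property_value``) read through :mod:`obonet`, with a read-only import
path for OWL/XML files restricted to asserted subClassOf axioms between
named classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.etree import ElementTree as ET

import networkx as nx
import obonet

from .errors import (
    DuplicateClassError,
    ParseError,
    UnknownClassError,
    ValidationError,
)

SEVERITY_LEVELS = ("borderline", "mild", "moderate", "severe", "profound")
LATERALITIES = ("left", "right", "bilateral")

_OWL_NS = "http://www.w3.org/2002/07/owl#"
_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"


class OwlImportWarning(UserWarning):
    """Raised (as a warning) when non-named-class axioms are skipped."""


@dataclass(frozen=True)
class OntologyClass:
    """One named phenotype class.

    ``parents`` holds the asserted ``is_a`` superclasses.  ``severity``
    and ``laterality`` are class-level qualifiers: a severity subclass
    such as ``moderate_dysarthria`` is fully determined by its base class
    and its level, so no property restrictions are needed.
    """

    id: str
    label: str
    parents: frozenset[str] = frozenset()
    severity: str | None = None
    laterality: str | None = None
    obsolete: bool = False

    def __post_init__(self):
        if self.severity is not None and self.severity not in SEVERITY_LEVELS:
            raise ValidationError(
                f"class {self.id!r}: severity {self.severity!r} not in "
                f"{SEVERITY_LEVELS}"
            )
        if self.laterality is not None and self.laterality not in LATERALITIES:
            raise ValidationError(
                f"class {self.id!r}: laterality {self.laterality!r} not in "
                f"{LATERALITIES}"
            )


class PhenotypeOntology:
    """A rooted, acyclic ``is_a`` hierarchy of :class:`OntologyClass`.

    Invariants checked on construction:

    * class ids are unique and every parent reference resolves;
    * the ``is_a`` graph is acyclic;
    * every non-root class reaches the root through its parents.
    """

    def __init__(self, classes, root: str):
        self.classes: dict[str, OntologyClass] = {}
        for cls in classes:
            if cls.id in self.classes:
                raise DuplicateClassError(f"duplicate class id {cls.id!r}")
            if not cls.obsolete:
                self.classes[cls.id] = cls
        if root not in self.classes:
            raise ValidationError(f"root class {root!r} not present")
        self.root = root
        self._graph = self._build_graph()

    def _build_graph(self) -> nx.DiGraph:
        dangling: list[str] = []
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for cls in self.classes.values():
            for parent in cls.parents:
                if parent not in self.classes:
                    dangling.append(f"{cls.id} -> {parent}")
                else:
                    g.add_edge(cls.id, parent)  # child -> parent
        if dangling:
            raise ValidationError("dangling parent reference(s)", sorted(dangling))
        if not nx.is_directed_acyclic_graph(g):
            cycle = sorted({u for u, _ in nx.find_cycle(g)})
            raise ValidationError(
                f"is_a graph contains a cycle through: {', '.join(cycle)}"
            )
        unreachable = [
            c for c in self.classes
            if c != self.root and not nx.has_path(g, c, self.root)
        ]
        if unreachable:
            raise ValidationError(
                "class(es) do not reach the root via is_a", sorted(unreachable)
            )
        return g

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def __getitem__(self, class_id: str) -> OntologyClass:
        self._require(class_id)
        return self.classes[class_id]

    def _require(self, *ids: str) -> None:
        missing = [i for i in ids if i not in self.classes]
        if missing:
            raise UnknownClassError(missing)

    def ancestors(self, class_id: str) -> set[str]:
        """Transitive ``is_a`` closure of ``class_id`` (excluding itself)."""
        self._require(class_id)
        return set(nx.descendants(self._graph, class_id))

    def descendants(self, class_id: str) -> set[str]:
        """All classes that have ``class_id`` as an ancestor."""
        self._require(class_id)
        return set(nx.ancestors(self._graph, class_id))

    def subclass_count(self, class_id: str | None = None) -> int:
        """Number of (transitive) subclasses of ``class_id`` (default root)."""
        return len(self.descendants(class_id or self.root))

    def classify_individual(self, asserted) -> set[str]:
        """Named-class subsumption closure of an individual's assertions.

        Returns ``asserted`` together with every ancestor of an asserted
        class — the inferred type set a DL reasoner would assign under
        pure ``subClassOf`` semantics.
        """
        asserted = set(asserted)
        self._require(*asserted)
        inferred = set(asserted)
        for class_id in asserted:
            inferred |= self.ancestors(class_id)
        return inferred

    # ------------------------------------------------------------------
    # editing (functional: each operation returns a new ontology)
    # ------------------------------------------------------------------
    def extract_module(self, seeds) -> "PhenotypeOntology":
        """Upward-closed sub-ontology induced by ``seeds`` and their ancestors.

        This is seed-based module (slim) extraction: the result contains
        every seed, every ancestor of a seed, and the ``is_a`` edges among
        the retained classes, and is itself a valid rooted ontology.
        """
        seeds = set(seeds)
        self._require(*seeds)
        keep = self.classify_individual(seeds) | {self.root}
        classes = [
            replace(cls, parents=frozenset(p for p in cls.parents if p in keep))
            for cid, cls in self.classes.items()
            if cid in keep
        ]
        return PhenotypeOntology(classes, self.root)

    def add_severity_subclasses(self, base: str, levels) -> "PhenotypeOntology":
        """Add one severity subclass of ``base`` per level.

        Generated ids follow the deterministic scheme ``<level>_<base>``
        (e.g. ``moderate_dysarthria``), with the level also recorded in
        the ``severity`` qualifier and the label derived from the base
        label.  The base class's laterality is inherited.
        """
        self._require(base)
        levels = list(levels)
        bad = [l for l in levels if l not in SEVERITY_LEVELS]
        if bad:
            raise ValidationError(f"unknown severity level(s): {bad}")
        new = []
        base_cls = self.classes[base]
        for level in levels:
            new_id = f"{level}_{base}"
            if new_id in self.classes:
                raise DuplicateClassError(
                    f"severity subclass {new_id!r} already exists"
                )
            new.append(OntologyClass(
                id=new_id,
                label=f"{level.capitalize()} {base_cls.label.lower()}",
                parents=frozenset({base}),
                severity=level,
                laterality=base_cls.laterality,
            ))
        return PhenotypeOntology(list(self.classes.values()) + new, self.root)

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """Child->parent ``is_a`` digraph with label/qualifier node data."""
        g = nx.DiGraph()
        for cid, cls in self.classes.items():
            g.add_node(cid, label=cls.label, severity=cls.severity,
                       laterality=cls.laterality)
        g.add_edges_from(self._graph.edges)
        return g

    def to_node_link(self, restrict=None) -> dict:
        """JSON-serializable node-link representation (optionally induced)."""
        g = self.to_networkx()
        if restrict is not None:
            g = g.subgraph(set(restrict)).copy()
        data = nx.node_link_data(g, edges="links")
        data["nodes"].sort(key=lambda n: n["id"])
        data["links"].sort(key=lambda e: (e["source"], e["target"]))
        return data

    def to_dot(self, restrict=None) -> str:
        """Graphviz DOT rendering of the ``is_a`` hierarchy."""
        keep = set(restrict) if restrict is not None else set(self.classes)
        lines = ["digraph phenotype {", "  rankdir=BT;"]
        for cid in sorted(keep):
            label = self.classes[cid].label.replace('"', r"\"")
            lines.append(f'  "{cid}" [label="{label}"];')
        for child, parent in sorted(self._graph.edges):
            if child in keep and parent in keep:
                lines.append(f'  "{child}" -> "{parent}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def __eq__(self, other) -> bool:
        return (isinstance(other, PhenotypeOntology)
                and self.root == other.root
                and self.classes == other.classes)


# ----------------------------------------------------------------------
# OBO flat-file subset
# ----------------------------------------------------------------------

def load_obo(path, root: str | None = None) -> PhenotypeOntology:
    """Load an ontology from an OBO 1.4 flat-file subset.

    Recognized per-term tags: ``id``, ``name``, ``is_a``, ``is_obsolete``
    and ``property_value`` lines for the ``has_severity`` /
    ``has_laterality`` qualifiers.  Obsolete terms are dropped.  When
    ``root`` is not given, the unique parentless class is taken as root.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # obonet warns on minimal headers
            graph = obonet.read_obo(path if hasattr(path, "read") else str(path))
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc

    classes = []
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # obonet materializes dangling is_a targets as empty nodes;
            # keep them out so validation reports the dangling reference.
            continue
        severity = laterality = None
        for pv in data.get("property_value", []):
            parts = pv.split()
            if len(parts) >= 2:
                key, value = parts[0], parts[1].strip('"')
                if key == "has_severity":
                    severity = value
                elif key == "has_laterality":
                    laterality = value
        classes.append(OntologyClass(
            id=node,
            label=data["name"],
            parents=frozenset(data.get("is_a", [])),
            severity=severity,
            laterality=laterality,
        ))
    return PhenotypeOntology(classes, root or _find_root(classes))


def _find_root(classes) -> str:
    roots = sorted(c.id for c in classes if not c.parents)
    if len(roots) != 1:
        raise ValidationError(
            f"expected exactly one parentless root class, found: {roots}"
        )
    return roots[0]


def write_obo(ont: PhenotypeOntology, path) -> None:
    """Serialize to the OBO subset read by :func:`load_obo` (stable order)."""
    lines = ["format-version: 1.2", "ontology: sarakit-phenotype", ""]
    for cid in sorted(ont.classes):
        cls = ont.classes[cid]
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        lines.append(f"name: {cls.label}")
        for parent in sorted(cls.parents):
            lines.append(f"is_a: {parent} ! {ont.classes[parent].label}")
        if cls.severity:
            lines.append(f'property_value: has_severity "{cls.severity}" xsd:string')
        if cls.laterality:
            lines.append(
                f'property_value: has_laterality "{cls.laterality}" xsd:string'
            )
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ----------------------------------------------------------------------
# OWL/XML (asserted named-class subClassOf axioms only)
# ----------------------------------------------------------------------

def import_owl_subclass_hierarchy(path, root: str | None = None) -> PhenotypeOntology:
    """Read the asserted named-class subClassOf skeleton of an OWL/XML file.

    Only ``owl:Class`` elements with an IRI and ``rdfs:subClassOf`` axioms
    whose filler is a named class are imported.  Anonymous superclasses
    (property restrictions, intersections, ...) are skipped; a single
    :class:`OwlImportWarning` reports how many axioms were dropped.
    Labels default to the IRI fragment when no ``rdfs:label`` is present.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ParseError(f"cannot parse OWL/XML file {path}: {exc}") from exc

    skipped = 0
    classes: dict[str, dict] = {}
    for el in tree.getroot().iter(f"{{{_OWL_NS}}}Class"):
        iri = el.get(f"{{{_RDF_NS}}}about") or el.get(f"{{{_RDF_NS}}}ID")
        if iri is None:
            continue  # anonymous class expression; handled at the axiom site
        cid = _fragment(iri)
        entry = classes.setdefault(cid, {"label": cid, "parents": set()})
        label_el = el.find(f"{{{_RDFS_NS}}}label")
        if label_el is not None and label_el.text:
            entry["label"] = label_el.text
        for sub in el.findall(f"{{{_RDFS_NS}}}subClassOf"):
            resource = sub.get(f"{{{_RDF_NS}}}resource")
            if resource is not None:
                entry["parents"].add(_fragment(resource))
                continue
            named = sub.find(f"{{{_OWL_NS}}}Class")
            named_iri = named.get(f"{{{_RDF_NS}}}about") if named is not None else None
            if named_iri is not None:
                entry["parents"].add(_fragment(named_iri))
            else:
                skipped += 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} non-named-class subClassOf axiom(s)",
            OwlImportWarning,
            stacklevel=2,
        )
    built = [
        OntologyClass(id=cid, label=e["label"], parents=frozenset(e["parents"]))
        for cid, e in classes.items()
    ]
    return PhenotypeOntology(built, root or _find_root(built))


def _fragment(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri


def write_owl(ont: PhenotypeOntology, path, base_iri="http://sarakit.local/pheno#"):
    """Write the ``is_a`` skeleton as OWL/XML (named subClassOf axioms only).

    Severity/laterality qualifiers are not expressible in this skeleton;
    the OBO format is the lossless native serialization.
    """
    ET.register_namespace("owl", _OWL_NS)
    ET.register_namespace("rdf", _RDF_NS)
    ET.register_namespace("rdfs", _RDFS_NS)
    rdf = ET.Element(f"{{{_RDF_NS}}}RDF")
    for cid in sorted(ont.classes):
        cls = ont.classes[cid]
        el = ET.SubElement(rdf, f"{{{_OWL_NS}}}Class",
                           {f"{{{_RDF_NS}}}about": base_iri + cid})
        label = ET.SubElement(el, f"{{{_RDFS_NS}}}label")
        label.text = cls.label
        for parent in sorted(cls.parents):
            ET.SubElement(el, f"{{{_RDFS_NS}}}subClassOf",
                          {f"{{{_RDF_NS}}}resource": base_iri + parent})
    ET.ElementTree(rdf).write(str(path), xml_declaration=True, encoding="unicode")


def load_sara_ontology() -> PhenotypeOntology:
    """Load the packaged SARA phenotype slim (109 abnormality subclasses)."""
    import io
    from importlib.resources import files

    text = files("sarakit.data").joinpath("sara_phenotype.obo").read_text()
    return load_obo(io.StringIO(text), root="phenotypic_abnormality")
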