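"""Readers, writers, validation, and OBO import/export for the five resource files.

File layout (CSV, UTF-8, no header row):

========================  ==========================================================
entities.csv              one column: identifier
relations.csv             subject_ns, subject_id, relation, object_ns, object_id
grounding_map.csv         text, target_ns, target_id
equivalences.csv          external_ns, external_id, famplex_id
gene_prefixes.csv         pattern, position, category[, species_tag]
========================  ==========================================================
"""

from __future__ import annotations

import csv
import io
from pathlib import Path

import networkx as nx

from .model import (
    DEFAULT_NAMESPACES,
    DEFAULT_OWN_NAMESPACE,
    Affix,
    AffixCategory,
    AffixPosition,
    EntityRef,
    Equivalence,
    GroundingEntry,
    Ontology,
    Relation,
    RelationType,
    ResourceError,
    Severity,
    ValidationIssue,
)

ENTITIES_FILE = "entities.csv"
RELATIONS_FILE = "relations.csv"
GROUNDING_MAP_FILE = "grounding_map.csv"
EQUIVALENCES_FILE = "equivalences.csv"
AFFIXES_FILE = "gene_prefixes.csv"


def _issue(issues, severity, code, message, location=""):
    issues.append(ValidationIssue(severity, code, message, location))


def _finish(issues_out, local_issues):
    """Either hand issues to the caller's accumulator or raise on errors."""
    if issues_out is not None:
        issues_out.extend(local_issues)
    else:
        errors = [i for i in local_issues if i.severity is Severity.ERROR]
        if errors:
            raise ResourceError(errors)


def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh)]


def load_entities(path: str | Path, issues: list[ValidationIssue] | None = None) -> set[str]:
    """Load the entity-identifier file into a set.

    Duplicate identifiers produce a ``duplicate_entity`` error; an empty file
    produces an ``empty_file`` warning and an empty set.
    """
    local: list[ValidationIssue] = []
    entities: set[str] = set()
    rows = _read_rows(path)
    if not rows:
        _issue(local, Severity.WARNING, "empty_file", "entities file is empty", str(path))
    for lineno, row in enumerate(rows, start=1):
        loc = f"{path}:{lineno}"
        if not row or not row[0].strip():
            _issue(local, Severity.ERROR, "malformed_row", "empty entity row", loc)
            continue
        ident = row[0].strip()
        if ident in entities:
            _issue(local, Severity.ERROR, "duplicate_entity",
                   f"duplicate entity {ident!r}", loc)
        entities.add(ident)
    _finish(issues, local)
    return entities


def load_relations(
    path: str | Path,
    issues: list[ValidationIssue] | None = None,
    namespaces: frozenset[str] = DEFAULT_NAMESPACES,
) -> list[Relation]:
    """Load relations in file order; ``rel`` is parsed into :class:`RelationType`."""
    local: list[ValidationIssue] = []
    relations: list[Relation] = []
    for lineno, row in enumerate(_read_rows(path), start=1):
        loc = f"{path}:{lineno}"
        if len(row) != 5:
            _issue(local, Severity.ERROR, "malformed_row",
                   f"expected 5 columns, got {len(row)}", loc)
            continue
        sns, sid, rel, ons, oid = (c.strip() for c in row)
        try:
            rtype = RelationType(rel)
        except ValueError:
            _issue(local, Severity.ERROR, "invalid_relation",
                   f"unknown relation token {rel!r}", loc)
            continue
        for ns in (sns, ons):
            if ns not in namespaces:
                _issue(local, Severity.WARNING, "unknown_namespace",
                       f"namespace {ns!r} not in controlled vocabulary", loc)
        try:
            relations.append(Relation(EntityRef(sns, sid), rtype, EntityRef(ons, oid)))
        except ValueError as exc:
            _issue(local, Severity.ERROR, "self_relation", str(exc), loc)
    _finish(issues, local)
    return relations


def load_grounding_map(
    path: str | Path, issues: list[ValidationIssue] | None = None
) -> dict[str, EntityRef]:
    """Load the synonym->identifier map; text keys are kept verbatim."""
    local: list[ValidationIssue] = []
    gmap: dict[str, EntityRef] = {}
    for lineno, row in enumerate(_read_rows(path), start=1):
        loc = f"{path}:{lineno}"
        if len(row) != 3:
            _issue(local, Severity.ERROR, "malformed_row",
                   f"expected 3 columns, got {len(row)}", loc)
            continue
        text, ns, ident = row[0], row[1].strip(), row[2].strip()
        if not text:
            _issue(local, Severity.ERROR, "malformed_row", "empty synonym text", loc)
            continue
        if text in gmap:
            _issue(local, Severity.ERROR, "duplicate_synonym",
                   f"duplicate grounding-map key {text!r}", loc)
            continue
        gmap[text] = EntityRef(ns, ident)
    _finish(issues, local)
    return gmap


def load_equivalences(
    path: str | Path, issues: list[ValidationIssue] | None = None
) -> list[Equivalence]:
    local: list[ValidationIssue] = []
    equivs: list[Equivalence] = []
    for lineno, row in enumerate(_read_rows(path), start=1):
        loc = f"{path}:{lineno}"
        if len(row) != 3:
            _issue(local, Severity.ERROR, "malformed_row",
                   f"expected 3 columns, got {len(row)}", loc)
            continue
        ns, ident, fid = (c.strip() for c in row)
        equivs.append(Equivalence(EntityRef(ns, ident), fid))
    _finish(issues, local)
    return equivs


_SPECIES_TAGS = {"mmu-{Gene name}": "mouse"}  # fallback for 3-column rows


def load_affixes(
    path: str | Path, issues: list[ValidationIssue] | None = None
) -> list[Affix]:
    """Load the affix table. Patterns without the placeholder are rejected."""
    local: list[ValidationIssue] = []
    affixes: list[Affix] = []
    for lineno, row in enumerate(_read_rows(path), start=1):
        loc = f"{path}:{lineno}"
        if len(row) not in (3, 4):
            _issue(local, Severity.ERROR, "malformed_row",
                   f"expected 3 or 4 columns, got {len(row)}", loc)
            continue
        pattern = row[0]
        try:
            position = AffixPosition(row[1].strip())
            category = AffixCategory(row[2].strip())
        except ValueError as exc:
            _issue(local, Severity.ERROR, "malformed_row", str(exc), loc)
            continue
        species = row[3].strip() if len(row) == 4 and row[3].strip() else None
        if species is None and category is AffixCategory.SPECIES:
            species = _SPECIES_TAGS.get(pattern)
        try:
            affixes.append(Affix(pattern, position, category, species))
        except ValueError as exc:
            _issue(local, Severity.ERROR, "malformed_affix", str(exc), loc)
    _finish(issues, local)
    return affixes


def load_ontology(
    directory: str | Path,
    issues: list[ValidationIssue] | None = None,
    own_namespace: str = DEFAULT_OWN_NAMESPACE,
    namespaces: frozenset[str] = DEFAULT_NAMESPACES,
) -> Ontology:
    """Load all five resource files from ``directory`` into an :class:`Ontology`."""
    d = Path(directory)
    return Ontology(
        entities=load_entities(d / ENTITIES_FILE, issues),
        relations=load_relations(d / RELATIONS_FILE, issues, namespaces),
        grounding_map=load_grounding_map(d / GROUNDING_MAP_FILE, issues),
        equivalences=load_equivalences(d / EQUIVALENCES_FILE, issues),
        affixes=load_affixes(d / AFFIXES_FILE, issues),
        own_namespace=own_namespace,
        namespaces=namespaces,
    )


def write_ontology(ontology: Ontology, directory: str | Path) -> None:
    """Write the five resource files with deterministic (sorted) ordering."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def _write(name: str, rows) -> None:
        with open(d / name, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerows(rows)

    _write(ENTITIES_FILE, ([e] for e in sorted(ontology.entities)))
    _write(
        RELATIONS_FILE,
        sorted(
            [r.subject.namespace, r.subject.identifier, r.rel.value,
             r.object.namespace, r.object.identifier]
            for r in ontology.relations
        ),
    )
    _write(
        GROUNDING_MAP_FILE,
        sorted(
            [text, ref.namespace, ref.identifier]
            for text, ref in ontology.grounding_map.items()
        ),
    )
    _write(
        EQUIVALENCES_FILE,
        sorted(
            [eq.external.namespace, eq.external.identifier, eq.famplex_id]
            for eq in ontology.equivalences
        ),
    )
    _write(
        AFFIXES_FILE,
        sorted(
            [a.pattern, a.position.value, a.category.value, a.species_tag or ""]
            for a in ontology.affixes
        ),
    )


def relation_graph(ontology: Ontology) -> nx.DiGraph:
    """Directed graph over relations, child -> parent, edge type as attribute."""
    g = nx.DiGraph()
    for ident in ontology.entities:
        g.add_node(ontology.ref(ident))
    for r in ontology.relations:
        g.add_edge(r.subject, r.object, rel=r.rel)
    return g


def validate(ontology: Ontology) -> list[ValidationIssue]:
    """Check every structural invariant; the empty list means the ontology is valid.

    Issues reported: dangling own-namespace relation endpoints, dangling
    equivalences, own-namespace grounding targets missing from the entity
    set, and cycles in the relation graph.
    """
    issues: list[ValidationIssue] = []
    own = ontology.own_namespace

    for i, r in enumerate(ontology.relations):
        for end, role in ((r.subject, "subject"), (r.object, "object")):
            if end.namespace == own and end.identifier not in ontology.entities:
                _issue(issues, Severity.ERROR, "dangling_relation",
                       f"relation {role} {end} not in entities",
                       f"{RELATIONS_FILE}:{i + 1}")

    for i, eq in enumerate(ontology.equivalences):
        if eq.famplex_id not in ontology.entities:
            _issue(issues, Severity.ERROR, "dangling_equivalence",
                   f"equivalence target {own}:{eq.famplex_id} not in entities",
                   f"{EQUIVALENCES_FILE}:{i + 1}")

    for text, ref in sorted(ontology.grounding_map.items()):
        if ref.namespace == own and ref.identifier not in ontology.entities:
            _issue(issues, Severity.ERROR, "dangling_grounding",
                   f"grounding target {ref} for {text!r} not in entities",
                   GROUNDING_MAP_FILE)

    g = relation_graph(ontology)
    if not nx.is_directed_acyclic_graph(g):
        for cyc in nx.simple_cycles(g):
            _issue(issues, Severity.ERROR, "cycle",
                   "relation cycle: " + " -> ".join(str(n) for n in cyc),
                   RELATIONS_FILE)

    return issues


# ---------------------------------------------------------------------------
# OBO export / import
# ---------------------------------------------------------------------------

_OBO_HEADER = "format-version: 1.2"
_PART_OF_TYPEDEF = "[Typedef]\nid: part_of\nname: part of\nis_transitive: true"


def _obo_id(ref: EntityRef) -> str:
    return f"{ref.namespace}:{ref.identifier}"


def export_obo(ontology: Ontology, ontology_name: str = "fplx") -> str:
    """Serialize the ontology as OBO 1.2 text.

    One ``[Term]`` stanza per node (own-namespace entities and the external
    gene-level leaves referenced by relations or the grounding map), sorted
    by id for diff-stable output. ``isa`` becomes ``is_a``, ``partof``
    becomes a ``part_of`` relationship, equivalences become ``xref`` lines,
    and grounding-map texts become ``synonym`` lines on their target's
    stanza. Refuses to export an ontology with validation errors.
    """
    problems = [i for i in validate(ontology) if i.severity is Severity.ERROR]
    if problems:
        raise ResourceError(problems)

    nodes: set[EntityRef] = {ontology.ref(e) for e in ontology.entities}
    for r in ontology.relations:
        nodes.update((r.subject, r.object))
    nodes.update(ontology.grounding_map.values())

    parents: dict[EntityRef, list[tuple[RelationType, EntityRef]]] = {}
    for r in ontology.relations:
        parents.setdefault(r.subject, []).append((r.rel, r.object))
    xrefs: dict[EntityRef, list[EntityRef]] = {}
    for eq in ontology.equivalences:
        xrefs.setdefault(ontology.ref(eq.famplex_id), []).append(eq.external)
    synonyms: dict[EntityRef, list[str]] = {}
    for text, ref in ontology.grounding_map.items():
        synonyms.setdefault(ref, []).append(text)

    out = io.StringIO()
    out.write(f"{_OBO_HEADER}\nontology: {ontology_name}\n")
    for node in sorted(nodes):
        out.write(f"\n[Term]\nid: {_obo_id(node)}\nname: {node.identifier}\n")
        for text in sorted(synonyms.get(node, [])):
            escaped = text.replace("\\", "\\\\").replace('"', '\\"')
            out.write(f'synonym: "{escaped}" EXACT []\n')
        for ext in sorted(xrefs.get(node, [])):
            out.write(f"xref: {_obo_id(ext)}\n")
        for rel, parent in sorted(parents.get(node, []), key=lambda p: (p[0].value, p[1])):
            if rel is RelationType.ISA:
                out.write(f"is_a: {_obo_id(parent)} ! {parent.identifier}\n")
            else:
                out.write(f"relationship: part_of {_obo_id(parent)} ! {parent.identifier}\n")
    out.write(f"\n{_PART_OF_TYPEDEF}\n")
    return out.getvalue()


class OboParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def _parse_ref(token: str, lineno: int) -> EntityRef:
    ns, sep, ident = token.partition(":")
    if not sep or not ns or not ident:
        raise OboParseError(lineno, f"malformed id {token!r}")
    return EntityRef(ns, ident)


def parse_obo(text: str, own_namespace: str = DEFAULT_OWN_NAMESPACE) -> Ontology:
    """Parse OBO text produced by :func:`export_obo` back into an :class:`Ontology`.

    Inverse of :func:`export_obo` on its image: entities, relations,
    grounding map and equivalences are reconstructed; affixes are not
    representable in OBO and come back empty.
    """
    ontology = Ontology(own_namespace=own_namespace)
    current: EntityRef | None = None
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = None
            if not in_term and line != "[Typedef]":
                raise OboParseError(lineno, f"unknown stanza {line}")
            continue
        if not in_term:
            continue
        key, sep, value = line.partition(": ")
        if not sep:
            raise OboParseError(lineno, f"malformed tag line {line!r}")
        value = value.split(" ! ")[0].strip()
        if key == "id":
            current = _parse_ref(value, lineno)
            if current.namespace == own_namespace:
                ontology.entities.add(current.identifier)
        elif current is None:
            raise OboParseError(lineno, f"{key} tag before id in stanza")
        elif key == "synonym":
            if not value.startswith('"'):
                raise OboParseError(lineno, f"malformed synonym {value!r}")
            # unescape the quoted synonym text
            chars: list[str] = []
            i = 1
            while i < len(value):
                c = value[i]
                if c == "\\" and i + 1 < len(value):
                    chars.append(value[i + 1])
                    i += 2
                    continue
                if c == '"':
                    break
                chars.append(c)
                i += 1
            ontology.grounding_map["".join(chars)] = current
        elif key == "xref":
            ontology.equivalences.append(
                Equivalence(_parse_ref(value, lineno), current.identifier)
            )
        elif key == "is_a":
            ontology.relations.append(
                Relation(current, RelationType.ISA, _parse_ref(value, lineno))
            )
        elif key == "relationship":
            rel, _, target = value.partition(" ")
            if rel != "part_of":
                raise OboParseError(lineno, f"unknown relationship type {rel!r}")
            ontology.relations.append(
                Relation(current, RelationType.PARTOF, _parse_ref(target.strip(), lineno))
            )
        # name and header-like tags carry no extra structure
    return ontology
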