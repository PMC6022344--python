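"""Multi-level hierarchy resolution over isa/partof relations.

Edges run child -> parent; both edge types are traversed identically (the
type survives as an edge attribute). Gene-level nodes are recognized by
namespace: anything outside the resource's own namespace is a gene leaf.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field

import networkx as nx

from .model import DEFAULT_OWN_NAMESPACE, EntityRef, Ontology


class LevelClass(str, enum.Enum):
    """Structural class of an own-namespace entry."""

    TOP = "top"                   # has >=1 child, no parent
    INTERMEDIATE = "intermediate"  # has parent and child
    PLACEHOLDER = "placeholder"   # no parent and no child


class GroundingLevel(str, enum.Enum):
    """Level of a grounding relative to a named top-level entry."""

    GENE = "gene"
    INTERMEDIATE = "intermediate"
    TOP = "top"


@dataclass
class HierarchyGraph:
    """The relation DAG plus the namespace that marks family/complex nodes."""

    graph: nx.DiGraph
    own_namespace: str = DEFAULT_OWN_NAMESPACE
    _gene_members_cache: dict[EntityRef, frozenset[EntityRef]] = field(
        default_factory=dict, repr=False
    )

    def __contains__(self, node: EntityRef) -> bool:
        return node in self.graph

    def is_gene(self, node: EntityRef) -> bool:
        return node.namespace != self.own_namespace

    def children(self, node: EntityRef) -> set[EntityRef]:
        return set(self.graph.predecessors(node))

    def parents(self, node: EntityRef) -> set[EntityRef]:
        return set(self.graph.successors(node))

    def own_nodes(self) -> list[EntityRef]:
        return sorted(n for n in self.graph if not self.is_gene(n))


def build_graph(ontology: Ontology) -> HierarchyGraph:
    """Build the child->parent DAG from an ontology's entities and relations."""
    g = nx.DiGraph()
    for ident in ontology.entities:
        g.add_node(ontology.ref(ident))
    for r in ontology.relations:
        g.add_edge(r.subject, r.object, rel=r.rel)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("relation graph contains a cycle")
    return HierarchyGraph(g, ontology.own_namespace)


def _require(graph: HierarchyGraph, node: EntityRef) -> None:
    if node not in graph.graph:
        raise KeyError(f"unknown node {node}")


def ancestors(graph: HierarchyGraph, node: EntityRef) -> set[EntityRef]:
    """All nodes reachable by following child->parent edges; excludes ``node``."""
    _require(graph, node)
    return set(nx.descendants(graph.graph, node))


def descendants(graph: HierarchyGraph, node: EntityRef) -> set[EntityRef]:
    """All nodes from which ``node`` is reachable; excludes ``node``."""
    _require(graph, node)
    return set(nx.ancestors(graph.graph, node))


def gene_members(graph: HierarchyGraph, node: EntityRef) -> set[EntityRef]:
    """Gene-level (external-namespace leaf) descendants of ``node``.

    A gene node returns itself; a placeholder family returns the empty set.
    """
    _require(graph, node)
    if node in graph._gene_members_cache:
        return set(graph._gene_members_cache[node])
    if graph.is_gene(node):
        members = frozenset({node})
    else:
        members = frozenset(
            m
            for child in graph.children(node)
            for m in gene_members(graph, child)
        )
    graph._gene_members_cache[node] = members
    return set(members)


def classify_levels(graph: HierarchyGraph) -> dict[str, LevelClass]:
    """Classify every own-namespace node as top, intermediate, or placeholder."""
    result: dict[str, LevelClass] = {}
    for node in graph.own_nodes():
        has_child = graph.graph.in_degree(node) > 0
        has_parent = graph.graph.out_degree(node) > 0
        if has_parent:
            # entries with a parent but no child are still "intermediate" by
            # exclusion; curated resources do not normally contain them
            result[node.identifier] = LevelClass.INTERMEDIATE
        elif has_child:
            result[node.identifier] = LevelClass.TOP
        else:
            result[node.identifier] = LevelClass.PLACEHOLDER
    return result


def subsumed_depth(graph: HierarchyGraph, node: EntityRef) -> int:
    """Length of the longest child-chain from ``node`` down to a gene leaf.

    A gene leaf (and a placeholder with no children) has depth 0; a family
    resolved directly to genes has depth 1.
    """
    _require(graph, node)
    depth: dict[EntityRef, int] = {}
    for n in nx.topological_sort(graph.graph):
        kids = list(graph.graph.predecessors(n))
        depth[n] = 1 + max(depth[k] for k in kids) if kids else 0
    return depth[node]


def child_count(graph: HierarchyGraph, node: EntityRef) -> int:
    """Number of direct children (isa or partof alike)."""
    _require(graph, node)
    return graph.graph.in_degree(node)


def child_stats(graph: HierarchyGraph) -> tuple[float, float, float]:
    """(mean, sample sd, median) of child counts over entries with >=1 child."""
    counts = [
        graph.graph.in_degree(n)
        for n in graph.own_nodes()
        if graph.graph.in_degree(n) > 0
    ]
    if not counts:
        raise ValueError("no own-namespace entries with children")
    mean = statistics.fmean(counts)
    sd = statistics.stdev(counts) if len(counts) > 1 else 0.0
    return mean, sd, float(statistics.median(counts))


def grounding_level(
    graph: HierarchyGraph, entity: EntityRef, top_entry: EntityRef
) -> GroundingLevel:
    """Classify ``entity`` within the sub-hierarchy rooted at ``top_entry``."""
    _require(graph, top_entry)
    if entity == top_entry:
        return GroundingLevel.TOP
    _require(graph, entity)
    if top_entry not in ancestors(graph, entity):
        raise ValueError(f"{entity} is not in the sub-hierarchy of {top_entry}")
    if graph.is_gene(entity):
        return GroundingLevel.GENE
    return GroundingLevel.INTERMEDIATE


def subhierarchy_nodes(graph: HierarchyGraph, top_entry: EntityRef) -> set[EntityRef]:
    """``top_entry`` together with all of its descendants."""
    return descendants(graph, top_entry) | {top_entry}
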