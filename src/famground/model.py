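"""Core domain types shared by every famground module.

The resource is a set of family/complex identifiers in its *own* namespace
(default ``FPLX``), a hierarchy of ``isa``/``partof`` relations connecting
them to each other and to gene-level identifiers in external namespaces, a
grounding map from surface strings to identifiers, cross-ontology
equivalences, and a table of case-sensitive gene-name affixes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

#: Namespace token used for the resource's own family/complex identifiers.
DEFAULT_OWN_NAMESPACE = "FPLX"

#: Default controlled vocabulary of namespaces accepted in resource files.
#: Callers may extend or replace it via the ``namespaces`` argument of the
#: loaders and of :class:`Ontology`.
DEFAULT_NAMESPACES = frozenset(
    {
        "FPLX",       # own namespace (families and complexes)
        "HGNC",       # human gene symbols (gene-level leaves)
        "UP",         # UniProt
        "BEL",        # OpenBEL
        "RE",         # Reactome
        "IP",         # InterPro
        "PF",         # Pfam
        "NXPFA",      # NextProt family
        "GO",         # Gene Ontology
        "NCIT",       # NCI Thesaurus
        "MESH",       # MeSH
        "CHEBI",      # small molecules occasionally present in grounding maps
    }
)

PLACEHOLDER = "{Gene name}"


class RelationType(str, enum.Enum):
    """Edge type in the hierarchy: family membership or complex membership."""

    ISA = "isa"
    PARTOF = "partof"


class AffixPosition(str, enum.Enum):
    PREFIX = "prefix"
    SUFFIX = "suffix"


class AffixCategory(str, enum.Enum):
    """Semantic categories of gene/protein affixes."""

    EXPERIMENTAL_CONTEXT = "experimental_context"
    PROTEIN_STATE = "protein_state"
    INHIBITION = "inhibition"
    GENERIC_DESCRIPTOR = "generic_descriptor"
    SPECIES = "species"
    MRNA_GROUNDING = "mrna_grounding"


class Severity(str, enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True, order=True)
class EntityRef:
    """A namespaced identifier for a gene, family, or complex."""

    namespace: str
    identifier: str

    def __post_init__(self) -> None:
        if not self.identifier or self.identifier != self.identifier.strip():
            raise ValueError(
                f"identifier must be non-empty with no surrounding whitespace: "
                f"{self.identifier!r}"
            )
        if not self.namespace:
            raise ValueError("namespace must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.namespace}:{self.identifier}"


@dataclass(frozen=True)
class Relation:
    """A typed edge (child ``subject`` -> parent ``object``) in the hierarchy."""

    subject: EntityRef
    rel: RelationType
    object: EntityRef

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"self-relation not allowed: {self.subject}")


@dataclass(frozen=True)
class Equivalence:
    """Cross-reference between an external identifier and an own-namespace id."""

    external: EntityRef
    famplex_id: str


@dataclass(frozen=True)
class GroundingEntry:
    """One grounding-map row: a verbatim surface string and its target."""

    text: str
    target: EntityRef

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("grounding-map text must be non-empty")


@dataclass(frozen=True)
class Affix:
    """A case-sensitive prefix/suffix pattern with one gene-name placeholder.

    ``pattern`` contains exactly one ``{Gene name}`` placeholder, e.g.
    ``mmu-{Gene name}`` or ``{Gene name} mRNA``.
    """

    pattern: str
    position: AffixPosition
    category: AffixCategory
    species_tag: str | None = None

    def __post_init__(self) -> None:
        if self.pattern.count(PLACEHOLDER) != 1:
            raise ValueError(
                f"affix pattern must contain exactly one {PLACEHOLDER!r} "
                f"placeholder: {self.pattern!r}"
            )
        if self.species_tag is not None and self.category is not AffixCategory.SPECIES:
            raise ValueError("species_tag only allowed for species-category affixes")

    @property
    def literal(self) -> str:
        """The fixed text surrounding the placeholder."""
        return self.pattern.replace(PLACEHOLDER, "")


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    code: str
    message: str
    location: str = ""

    def __str__(self) -> str:
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity.value}: {self.code}: {self.message}{loc}"


#: Documented enumeration of issue codes emitted by loaders and validate().
ISSUE_CODES = frozenset(
    {
        "duplicate_entity",
        "duplicate_synonym",
        "invalid_relation",
        "malformed_row",
        "malformed_affix",
        "empty_file",
        "unknown_namespace",
        "dangling_relation",
        "dangling_equivalence",
        "dangling_grounding",
        "cycle",
        "self_relation",
    }
)


@dataclass
class Ontology:
    """The full resource: entities, relations, grounding map, equivalences, affixes."""

    entities: set[str] = field(default_factory=set)
    relations: list[Relation] = field(default_factory=list)
    grounding_map: dict[str, EntityRef] = field(default_factory=dict)
    equivalences: list[Equivalence] = field(default_factory=list)
    affixes: list[Affix] = field(default_factory=list)
    own_namespace: str = DEFAULT_OWN_NAMESPACE
    namespaces: frozenset[str] = DEFAULT_NAMESPACES

    def ref(self, identifier: str) -> EntityRef:
        """An :class:`EntityRef` for an own-namespace identifier."""
        return EntityRef(self.own_namespace, identifier)

    def synonyms_of(self, target: EntityRef) -> list[str]:
        """All grounding-map texts mapping to ``target``, sorted."""
        return sorted(t for t, e in self.grounding_map.items() if e == target)


class ResourceError(Exception):
    """Raised when a resource file contains error-severity issues."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        super().__init__("; ".join(str(i) for i in issues))
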