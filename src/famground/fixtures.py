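"""Deterministic fixtures: the worked-example ontology and seeded synthetic
ontologies/corpora, so every module is testable with no download.

Conventions (not literature facts): PLCB and PLCD are assigned 4 and 3
member genes so the three phospholipase C subfamilies total nine genes and
the sub-hierarchy holds 15 nodes; AMPK subunit isoform counts (2/2/3) use
the standard PRKA* symbols.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field

from .eval_stats import AnnotationCategory
from .model import (
    Affix,
    AffixCategory,
    AffixPosition,
    EntityRef,
    Equivalence,
    Ontology,
    Relation,
    RelationType,
)

GENE_NS = "HGNC"

_ISA = RelationType.ISA
_PARTOF = RelationType.PARTOF

#: The canonical example affixes, one per semantic category, plus the
#: siRNA suffix needed for polarity-inversion behavior.
EXAMPLE_AFFIXES: tuple[Affix, ...] = (
    Affix("eGFP-{Gene name}", AffixPosition.PREFIX, AffixCategory.EXPERIMENTAL_CONTEXT),
    Affix("phospho-{Gene name}", AffixPosition.PREFIX, AffixCategory.PROTEIN_STATE),
    Affix("shRNA-{Gene name}", AffixPosition.PREFIX, AffixCategory.INHIBITION),
    Affix("{Gene name} siRNA", AffixPosition.SUFFIX, AffixCategory.INHIBITION),
    Affix("proto-oncogene {Gene name}", AffixPosition.PREFIX, AffixCategory.GENERIC_DESCRIPTOR),
    Affix("mmu-{Gene name}", AffixPosition.PREFIX, AffixCategory.SPECIES, "mouse"),
    Affix("{Gene name} mRNA", AffixPosition.SUFFIX, AffixCategory.MRNA_GROUNDING),
)

# family/complex structure of the worked-example ontology:
# entity -> list of (child id, child namespace, relation type)
_STRUCTURE: dict[str, list[tuple[str, str, RelationType]]] = {
    "NFkappaB": [
        ("RELA", GENE_NS, _PARTOF),
        ("RELB", GENE_NS, _PARTOF),
        ("REL", GENE_NS, _PARTOF),
        ("NFKB1", GENE_NS, _PARTOF),
        ("NFKB2", GENE_NS, _PARTOF),
    ],
    "ERK": [("MAPK1", GENE_NS, _ISA), ("MAPK3", GENE_NS, _ISA)],
    "AMPK": [
        ("AMPK_alpha", "FPLX", _PARTOF),
        ("AMPK_beta", "FPLX", _PARTOF),
        ("AMPK_gamma", "FPLX", _PARTOF),
    ],
    "AMPK_alpha": [("PRKAA1", GENE_NS, _ISA), ("PRKAA2", GENE_NS, _ISA)],
    "AMPK_beta": [("PRKAB1", GENE_NS, _ISA), ("PRKAB2", GENE_NS, _ISA)],
    "AMPK_gamma": [
        ("PRKAG1", GENE_NS, _ISA),
        ("PRKAG2", GENE_NS, _ISA),
        ("PRKAG3", GENE_NS, _ISA),
    ],
    "PLC": [
        ("PLCB", "FPLX", _ISA),
        ("PLCG", "FPLX", _ISA),
        ("PLCD", "FPLX", _ISA),
        ("PLCE1", GENE_NS, _ISA),
        ("PLCZ1", GENE_NS, _ISA),
    ],
    "PLCB": [(f"PLCB{i}", GENE_NS, _ISA) for i in (1, 2, 3, 4)],
    "PLCG": [("PLCG1", GENE_NS, _ISA), ("PLCG2", GENE_NS, _ISA)],
    "PLCD": [(f"PLCD{i}", GENE_NS, _ISA) for i in (1, 3, 4)],
    "RAS": [("KRAS", GENE_NS, _ISA), ("NRAS", GENE_NS, _ISA), ("HRAS", GENE_NS, _ISA)],
    "RAF": [("ARAF", GENE_NS, _ISA), ("BRAF", GENE_NS, _ISA), ("RAF1", GENE_NS, _ISA)],
    # broad functional categories with no curated relations
    "GTPase": [],
    "Phosphatase": [],
    "Protease": [],
}

_EXTRA_SYNONYMS: dict[str, list[str]] = {
    "NFkappaB": ["NF-kB", "NF-kappaB", "NF-kappaB TFs"],
    "ERK": ["ERK 1/2", "ERKs", "Extracellular Signal Regulated Kinase"],
    "PLCG": ["PLCgamma"],
    "RAS": ["Ras"],
    "PLC": ["Phospholipase C"],
}

_EQUIVALENCES: list[tuple[str, str, str]] = [
    ("IP", "IPR020849", "RAS"),
    ("RE", "R-HSA-1280218", "AMPK"),
    ("GO", "GO:0071159", "NFkappaB"),
    ("NXPFA", "03114", "PLC"),
]


def build_inpaper_ontology() -> Ontology:
    """The worked-example ontology used throughout the documentation and tests.

    Contains the NFkappaB complex (5 genes), the ERK family, the AMPK
    complex with three subunit families (2/2/3 isoforms), the PLC hierarchy
    (3 subfamilies with 9 genes total plus 2 direct gene members; 15 nodes),
    RAS and RAF, three placeholder categories, and the example affixes.
    """
    ontology = Ontology(affixes=list(EXAMPLE_AFFIXES))
    for parent, children in _STRUCTURE.items():
        ontology.entities.add(parent)
        ontology.grounding_map.setdefault(parent, ontology.ref(parent))
        for child_id, ns, rel in children:
            child = EntityRef(ns, child_id)
            ontology.relations.append(Relation(child, rel, ontology.ref(parent)))
            if ns == GENE_NS:
                ontology.grounding_map.setdefault(child_id, child)
    for target, texts in _EXTRA_SYNONYMS.items():
        for text in texts:
            ontology.grounding_map[text] = ontology.ref(target)
    for ns, ident, fid in _EQUIVALENCES:
        ontology.equivalences.append(Equivalence(EntityRef(ns, ident), fid))
    return ontology


def generate_ontology(
    seed: int,
    n_families: int = 10,
    max_depth: int = 2,
    branching: int = 4,
    subfamily_probability: float = 0.5,
) -> Ontology:
    """Generate a random valid ontology, deterministic per seed.

    Each of ``n_families`` top-level families expands into at most
    ``branching`` children per node; a child is a subfamily with
    ``subfamily_probability`` while depth remains, otherwise a gene leaf.
    Every entity and gene gets at least one grounding-map synonym.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = random.Random(seed)
    ontology = Ontology(affixes=list(EXAMPLE_AFFIXES))
    gene_counter = 0

    def expand(parent: str, budget: int) -> None:
        nonlocal gene_counter
        for _ in range(rng.randint(1, branching)):
            if budget > 1 and rng.random() < subfamily_probability:
                child = f"{parent}S{sum(1 for e in ontology.entities if e.startswith(parent + 'S'))}"
                ontology.entities.add(child)
                ontology.grounding_map[child] = ontology.ref(child)
                rel = rng.choice([_ISA, _PARTOF])
                ontology.relations.append(
                    Relation(ontology.ref(child), rel, ontology.ref(parent))
                )
                expand(child, budget - 1)
            else:
                gene_counter += 1
                gene = EntityRef(GENE_NS, f"GN{gene_counter}")
                ontology.grounding_map[gene.identifier] = gene
                ontology.relations.append(
                    Relation(gene, rng.choice([_ISA, _PARTOF]), ontology.ref(parent))
                )

    for i in range(n_families):
        fam = f"FAM{i}"
        ontology.entities.add(fam)
        ontology.grounding_map[fam] = ontology.ref(fam)
        ontology.grounding_map[f"{fam} family"] = ontology.ref(fam)
        expand(fam, rng.randint(1, max_depth))
        if rng.random() < 0.5:
            ontology.equivalences.append(
                Equivalence(EntityRef("RE", f"R-HSA-{1000 + i}"), fam)
            )
    return ontology


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters for a seeded synthetic mention corpus."""

    seed: int
    n_mentions: int
    affix_probability: float = 0.0
    noise_probability: float = 0.0
    category_mix: dict[AnnotationCategory, float] = field(
        default_factory=lambda: {
            AnnotationCategory.FAMILY_COMPLEX: 0.5,
            AnnotationCategory.PROTEIN_GENE: 0.5,
        }
    )

    def __post_init__(self) -> None:
        for p in (self.affix_probability, self.noise_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range: {p}")
        if self.n_mentions < 0:
            raise ValueError("n_mentions must be >= 0")
        if not self.category_mix or any(w < 0 for w in self.category_mix.values()):
            raise ValueError("category_mix must be non-empty with nonnegative weights")


@dataclass(frozen=True)
class GoldMention:
    """A decorated surface string with its gold target entity."""

    text: str
    true_entity: EntityRef
    decorations: tuple[Affix, ...] = ()
    noised: bool = False


_NOISE_ALPHABET = string.ascii_lowercase + string.digits


def _apply_noise(text: str, rng: random.Random) -> str:
    """One random character substitution, deletion, or insertion."""
    op = rng.choice(("sub", "del", "ins"))
    pos = rng.randrange(len(text)) if text else 0
    if op == "sub" and text:
        replacement = rng.choice([c for c in _NOISE_ALPHABET if c != text[pos]])
        return text[:pos] + replacement + text[pos + 1:]
    if op == "del" and len(text) > 1:
        return text[:pos] + text[pos + 1:]
    return text[:pos] + rng.choice(_NOISE_ALPHABET) + text[pos:]


def generate_corpus(ontology: Ontology, spec: SyntheticCorpusSpec) -> list[GoldMention]:
    """Sample gold-labeled mentions from the ontology's grounding map.

    Targets are drawn per ``category_mix`` (family/complex = own-namespace
    targets, protein/gene = external targets); the surface form is a random
    synonym, optionally decorated with one random affix and optionally
    perturbed by one character edit.
    """
    rng = random.Random(spec.seed)
    by_category: dict[AnnotationCategory, list[EntityRef]] = {
        AnnotationCategory.FAMILY_COMPLEX: sorted(
            {r for r in ontology.grounding_map.values() if r.namespace == ontology.own_namespace}
        ),
        AnnotationCategory.PROTEIN_GENE: sorted(
            {r for r in ontology.grounding_map.values() if r.namespace != ontology.own_namespace}
        ),
    }
    categories = sorted(spec.category_mix, key=lambda c: c.value)
    weights = [spec.category_mix[c] for c in categories]
    for cat in categories:
        if not by_category.get(cat):
            raise ValueError(f"no grounding-map targets available for category {cat.value}")

    mentions: list[GoldMention] = []
    for _ in range(spec.n_mentions):
        category = rng.choices(categories, weights=weights)[0]
        target = rng.choice(by_category[category])
        synonyms = ontology.synonyms_of(target)
        if not synonyms:
            raise ValueError(f"entity {target} has no synonyms")
        text = rng.choice(synonyms)
        decorations: tuple[Affix, ...] = ()
        if ontology.affixes and rng.random() < spec.affix_probability:
            affix = rng.choice(sorted(ontology.affixes, key=lambda a: a.pattern))
            text = affix.pattern.replace("{Gene name}", text)
            decorations = (affix,)
        noised = rng.random() < spec.noise_probability
        if noised:
            text = _apply_noise(text, rng)
        mentions.append(GoldMention(text, target, decorations, noised))
    return mentions
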