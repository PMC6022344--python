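"""Affix stripping and grounding of entity strings.

Grounding is strip-then-lookup: case-sensitive affixes are removed
iteratively (longest literal first, prefixes before suffixes on ties, until
no affix applies), then the core string is looked up in the grounding map.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from . import hierarchy
from .model import Affix, AffixCategory, AffixPosition, EntityRef, Ontology

_WS = re.compile(r"\s+")


class MatchPolicy(str, enum.Enum):
    """Grounding-map lookup policy."""

    EXACT = "exact"
    CASE_INSENSITIVE_FALLBACK = "case_insensitive_fallback"


@dataclass(frozen=True)
class AffixMatch:
    """One affix removed from a mention, with its derived semantics."""

    affix: Affix
    matched_span: str

    @property
    def polarity_inverted(self) -> bool:
        return self.affix.category is AffixCategory.INHIBITION

    @property
    def species(self) -> str | None:
        return self.affix.species_tag if self.affix.category is AffixCategory.SPECIES else None

    @property
    def state_modifiers(self) -> list[str]:
        if self.affix.category is AffixCategory.PROTEIN_STATE:
            return [self.matched_span.strip("- ")]
        return []

    @property
    def is_mrna(self) -> bool:
        return self.affix.category is AffixCategory.MRNA_GROUNDING


@dataclass(frozen=True)
class GroundingResult:
    """Outcome of grounding a single text string."""

    input_text: str
    core_text: str
    entity: EntityRef | None
    affix_matches: tuple[AffixMatch, ...] = ()

    @property
    def polarity_inverted(self) -> bool:
        return any(m.polarity_inverted for m in self.affix_matches)

    @property
    def species(self) -> str | None:
        for m in self.affix_matches:
            if m.species is not None:
                return m.species
        return None

    @property
    def state_modifiers(self) -> list[str]:
        return [s for m in self.affix_matches for s in m.state_modifiers]

    @property
    def is_mrna(self) -> bool:
        return any(m.is_mrna for m in self.affix_matches)

    @property
    def grounded(self) -> bool:
        return self.entity is not None


def normalize_whitespace(text: str) -> str:
    return _WS.sub(" ", text.strip())


def _sorted_affixes(affixes: list[Affix]) -> list[Affix]:
    # longest literal first; prefixes before suffixes on literal-length ties
    return sorted(
        affixes,
        key=lambda a: (-len(a.literal), a.position is not AffixPosition.PREFIX, a.pattern),
    )


def strip_affixes(text: str, affixes: list[Affix]) -> tuple[str, list[AffixMatch]]:
    """Iteratively remove case-sensitive affixes from ``text`` to a fixpoint.

    Returns the core string and the matches in removal order. A match is
    only taken when a non-empty core remains, so an affix literal alone is
    never consumed to nothing.
    """
    core = normalize_whitespace(text)
    matches: list[AffixMatch] = []
    ordered = _sorted_affixes(affixes)
    changed = True
    while changed:
        changed = False
        for affix in ordered:
            lit = affix.literal
            if not lit:
                continue
            if affix.position is AffixPosition.PREFIX and core.startswith(lit):
                remainder = core[len(lit):]
            elif affix.position is AffixPosition.SUFFIX and core.endswith(lit):
                remainder = core[: len(core) - len(lit)]
            else:
                continue
            remainder = remainder.strip()
            if not remainder:
                continue
            matches.append(AffixMatch(affix, lit))
            core = remainder
            changed = True
            break
    return core, matches


def _casefold_index(ontology: Ontology) -> dict[str, EntityRef]:
    # deterministic under key collisions: lexicographically smallest original key wins
    index: dict[str, tuple[str, EntityRef]] = {}
    for text in sorted(ontology.grounding_map):
        folded = text.casefold()
        if folded not in index:
            index[folded] = (text, ontology.grounding_map[text])
    return {k: v[1] for k, v in index.items()}


def ground(
    text: str,
    ontology: Ontology,
    policy: MatchPolicy | str = MatchPolicy.EXACT,
) -> GroundingResult:
    """Strip affixes from ``text``, then look the core up in the grounding map."""
    policy = MatchPolicy(policy)
    core, matches = strip_affixes(text, ontology.affixes)
    entity = ontology.grounding_map.get(core)
    if entity is None and policy is MatchPolicy.CASE_INSENSITIVE_FALLBACK:
        entity = _casefold_index(ontology).get(core.casefold())
    return GroundingResult(text, core, entity, tuple(matches))


def ground_and_expand(
    text: str,
    ontology: Ontology,
    policy: MatchPolicy | str = MatchPolicy.EXACT,
    graph: hierarchy.HierarchyGraph | None = None,
) -> tuple[GroundingResult, set[EntityRef]]:
    """Ground ``text`` and expand the result to its gene-level members.

    The second element is empty when the text is ungrounded, the entity is
    absent from the hierarchy, or the entity is a placeholder.
    """
    result = ground(text, ontology, policy)
    if result.entity is None:
        return result, set()
    if graph is None:
        graph = hierarchy.build_graph(ontology)
    if result.entity not in graph:
        return result, set()
    return result, hierarchy.gene_members(graph, result.entity)
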