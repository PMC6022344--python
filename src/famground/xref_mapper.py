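"""Curation-support computations: cross-ontology equivalence proposal by
member-set comparison, and synonym candidate discovery by edit distance.

Proposals are suggestions for a curator, never auto-merged into the
equivalences file.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .model import EntityRef

#: family/complex ref -> set of gene-level member refs (shared gene namespace)
MemberTable = dict[EntityRef, set[EntityRef]]


class MatchMode(str, enum.Enum):
    EXACT_SET = "exact_set"
    SUBSET = "subset"
    JACCARD = "jaccard"


@dataclass(frozen=True)
class EquivalenceProposal:
    famplex_id: str
    external: EntityRef
    match_mode: MatchMode
    score: float


@dataclass(frozen=True)
class SynonymCandidate:
    entity_name: str
    corpus_string: str
    distance: int
    similarity: float


def jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def propose_equivalences(
    famplex_members: MemberTable,
    external_members: MemberTable,
    mode: MatchMode | str = MatchMode.EXACT_SET,
    threshold: float = 0.8,
) -> list[EquivalenceProposal]:
    """Propose external equivalents for each family by member-set comparison.

    ``exact_set`` proposes only identical member sets (score 1); ``subset``
    proposes externals whose members contain the family's members, scored by
    Jaccard; ``jaccard`` proposes all pairs with Jaccard >= ``threshold``.
    Results are sorted by (famplex_id, score descending, external). Entries
    with empty member sets are skipped with a warning.
    """
    mode = MatchMode(mode)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    proposals: list[EquivalenceProposal] = []
    for fam, fam_set in sorted(famplex_members.items()):
        if not fam_set:
            warnings.warn(f"skipping {fam}: empty member set", stacklevel=2)
            continue
        for ext, ext_set in sorted(external_members.items()):
            if not ext_set:
                warnings.warn(f"skipping {ext}: empty member set", stacklevel=2)
                continue
            score = jaccard(fam_set, ext_set)
            if mode is MatchMode.EXACT_SET:
                if fam_set != ext_set:
                    continue
            elif mode is MatchMode.SUBSET:
                if not fam_set <= ext_set:
                    continue
            elif score < threshold:
                continue
            proposals.append(EquivalenceProposal(fam.identifier, ext, mode, score))
    proposals.sort(key=lambda p: (p.famplex_id, -p.score, p.external))
    return proposals


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = curr
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized similarity 1 - d/max(|a|, |b|); identical strings give 1.0."""
    if a == b:
        return 1.0
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein(a, b) / longest


def propose_synonyms(
    entity_names: list[str],
    corpus_strings: list[str],
    threshold: float = 0.8,
    case_fold: bool = False,
) -> list[SynonymCandidate]:
    """Pair entity names with similar corpus strings by edit distance.

    Returns candidates with similarity >= ``threshold``, sorted by
    similarity descending then lexicographically. Distance is
    case-sensitive unless ``case_fold`` is set.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    candidates: list[SynonymCandidate] = []
    for name in entity_names:
        for corpus in corpus_strings:
            a, b = (name.casefold(), corpus.casefold()) if case_fold else (name, corpus)
            dist = levenshtein(a, b)
            sim = similarity(a, b)
            if sim >= threshold:
                candidates.append(SynonymCandidate(name, corpus, dist, sim))
    candidates.sort(key=lambda c: (-c.similarity, c.entity_name, c.corpus_string))
    return candidates
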