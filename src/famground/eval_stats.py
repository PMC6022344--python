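"""Grounding-evaluation statistics.

Covers per-category accuracy tables with binomial standard errors,
cumulative ungrounded-occurrence curves and top-percentile shares,
event-coverage proportions, multi-level grounding distributions, and
string-match coverage arithmetic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from . import hierarchy
from .hierarchy import GroundingLevel, HierarchyGraph
from .model import EntityRef


class AnnotationCategory(str, enum.Enum):
    PROTEIN_GENE = "protein_gene"
    FAMILY_COMPLEX = "family_complex"
    SMALL_MOLECULE = "small_molecule"
    BIO_PROCESS = "bio_process"
    MICRO_RNA = "micro_rna"
    OTHER_UNKNOWN = "other_unknown"


@dataclass(frozen=True)
class AnnotationSample:
    category: AnnotationCategory
    correct: bool


@dataclass(frozen=True)
class AccuracyRow:
    """One accuracy-table row; *_pct fields are unrounded percentages."""

    category: AnnotationCategory
    k_category: int
    entity_pct: float
    k_correct: int
    correct_pct: float
    se_pct: float

    @property
    def display(self) -> tuple[float, float, float]:
        """(entity %, correct %, SE %) rounded half-up to one decimal."""
        return (
            round_half_up(self.entity_pct),
            round_half_up(self.correct_pct),
            round_half_up(self.se_pct),
        )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching hand-computed table entries."""
    factor = 10 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def standard_error(k: int, n: int) -> float:
    """Binomial standard error sqrt((k/n)(1-k/n)/n) as a fraction in [0, 0.5]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    return math.sqrt(p * (1.0 - p) / n)


def accuracy_table(samples: list[AnnotationSample]) -> list[AccuracyRow]:
    """Per-category counts, percentages, and standard errors.

    ``entity_pct`` is the category's share of all samples; ``correct_pct``
    and ``se_pct`` use within-category counts. Rows appear in the canonical
    category order for the categories present.
    """
    if not samples:
        raise ValueError("sample list must be non-empty")
    total = len(samples)
    rows: list[AccuracyRow] = []
    for category in AnnotationCategory:
        in_cat = [s for s in samples if s.category is category]
        if not in_cat:
            continue
        n = len(in_cat)
        k = sum(s.correct for s in in_cat)
        rows.append(
            AccuracyRow(
                category=category,
                k_category=n,
                entity_pct=100.0 * n / total,
                k_correct=k,
                correct_pct=100.0 * k / n,
                se_pct=100.0 * standard_error(k, n),
            )
        )
    return rows


@dataclass(frozen=True)
class FrequencyCurve:
    """Cumulative occurrence shares over distinct strings ordered by frequency.

    ``points[i] = (percentile of distinct strings included, cumulative
    fraction of occurrences covered)`` after including the i+1 most frequent
    strings (count ties broken lexicographically).
    """

    points: tuple[tuple[float, float], ...]


def cumulative_curve(freqs: dict[str, int]) -> FrequencyCurve:
    """Cumulative-occurrence curve of a string-frequency table."""
    if not freqs:
        raise ValueError("frequency table must be non-empty")
    if any(c < 1 for c in freqs.values()):
        raise ValueError("occurrence counts must be >= 1")
    ordered = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(c for _, c in ordered)
    n = len(ordered)
    points = []
    cumulative = 0
    for i, (_, count) in enumerate(ordered, start=1):
        cumulative += count
        points.append((100.0 * i / n, cumulative / total))
    return FrequencyCurve(tuple(points))


def top_share(freqs: dict[str, int], occurrence_fraction: float) -> float:
    """Smallest distinct-string percentile covering >= ``occurrence_fraction``
    of all occurrences."""
    if not 0.0 <= occurrence_fraction <= 1.0:
        raise ValueError("occurrence_fraction must be in [0, 1]")
    for pct, cum in cumulative_curve(freqs).points:
        if cum >= occurrence_fraction:
            return pct
    return 100.0  # unreachable: final cumulative share is 1.0


@dataclass(frozen=True)
class EventCoverage:
    n_events: int
    n_any_ungrounded: int
    n_all_ungrounded: int

    @property
    def any_ungrounded_fraction(self) -> float:
        return self.n_any_ungrounded / self.n_events

    @property
    def all_ungrounded_fraction(self) -> float:
        return self.n_all_ungrounded / self.n_events


def event_coverage(events: list[list[bool]]) -> EventCoverage:
    """Proportions of events with any / all entities ungrounded.

    ``events`` holds one grounded-flag list per event (True = grounded).
    """
    if not events:
        raise ValueError("event list must be non-empty")
    if any(not flags for flags in events):
        raise ValueError("every event needs at least one entity flag")
    n_any = sum(1 for flags in events if not all(flags))
    n_all = sum(1 for flags in events if not any(flags))
    return EventCoverage(len(events), n_any, n_all)


def level_distribution(
    groundings: list[EntityRef],
    graph: HierarchyGraph,
    top_entry: EntityRef,
) -> dict[GroundingLevel, float]:
    """Fraction of groundings at gene / intermediate / top level within the
    sub-hierarchy of ``top_entry``. Fractions sum to 1."""
    if not groundings:
        raise ValueError("grounding list must be non-empty")
    counts = {level: 0 for level in GroundingLevel}
    for entity in groundings:
        counts[hierarchy.grounding_level(graph, entity, top_entry)] += 1
    total = len(groundings)
    return {level: c / total for level, c in counts.items() if c > 0}


def coverage_percentage(n_matched: int, n_total: int, n_excluded: int = 0) -> float:
    """Percentage matched after removing ``n_excluded`` from the denominator,
    rounded half-up to one decimal."""
    denominator = n_total - n_excluded
    if denominator < 1:
        raise ValueError("denominator must be >= 1 after exclusions")
    if not 0 <= n_matched <= denominator:
        raise ValueError("matched count must be within the denominator")
    return round_half_up(100.0 * n_matched / denominator)
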