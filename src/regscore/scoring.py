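"""The 0-10 regulatory evidence score.

Five independent lines of evidence, each worth 2 points, are summed into
an integer score between 0 and 10:

* chromatin accessibility — DNase I hotspot overlap (2 points)
* histone marks — ChIP-seq broadPeak overlap (2 points)
* transcription-factor binding — motif overlap (1 point) and an
  allele-specific TF-occupancy (CATO) record (1 point), jointly one line
* 3D contact — activity-by-contact enhancer interaction overlap (2 points)
* expression — a significant eQTL record (2 points)

Presence is binary: no partial credit, no weighting by how many tissues or
tracks support an indicator.  The point values are data, not code, so a
sensitivity analysis can re-weight without touching the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .evidence import (
    SCORED_CATEGORIES,
    EvidenceCatalog,
    EvidenceProfile,
    Variant,
    evaluate,
)

__all__ = [
    "ScoreScheme",
    "ScoreBreakdown",
    "ScoredVariant",
    "score_profile",
    "score_variants",
    "score_histogram",
]


@dataclass(frozen=True)
class ScoreScheme:
    """Points per indicator.  Defaults are the published scheme: five lines
    of evidence at 2 points each (TF motif 1 + CATO 1 jointly form the
    TF-binding line), total 10."""

    dnase: int = 2
    histone: int = 2
    tf_motif: int = 1
    cato: int = 1
    abc: int = 2
    eqtl: int = 2

    #: indicator groups forming the lines of evidence
    LINES = (
        ("dnase",),
        ("histone",),
        ("tf_motif", "cato"),
        ("abc",),
        ("eqtl",),
    )

    def points(self, category: str) -> int:
        return getattr(self, category)

    @property
    def max_score(self) -> int:
        return sum(self.points(c) for c in SCORED_CATEGORIES)

    @property
    def lines_of_evidence(self) -> int:
        return len(self.LINES)

    def line_points(self) -> list[int]:
        return [sum(self.points(c) for c in line) for line in self.LINES]

    def validate(self) -> None:
        if self.max_score != 10:
            raise ValueError(f"scheme total {self.max_score} != 10")
        if any(p != 2 for p in self.line_points()):
            raise ValueError(
                f"each line of evidence must carry 2 points, got {self.line_points()}"
            )

    @classmethod
    def from_mapping(cls, weights: Mapping[str, int]) -> "ScoreScheme":
        unknown = set(weights) - set(SCORED_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown scheme categories: {sorted(unknown)}")
        return cls(**dict(weights))


DEFAULT_SCHEME = ScoreScheme()


@dataclass
class ScoreBreakdown:
    """Per-indicator awarded points and their total for one profile."""

    awarded: dict[str, int]
    total: int
    profile: EvidenceProfile

    def __post_init__(self) -> None:
        if self.total != sum(self.awarded.values()):
            raise ValueError("total does not equal sum of awarded points")


@dataclass
class ScoredVariant:
    """One output record of the annotation pipeline (alleles merged per rsID)."""

    variant: Variant
    alts: list[str]
    profile: EvidenceProfile
    breakdown: ScoreBreakdown
    categories_missing: list[str]

    @property
    def score(self) -> int:
        return self.breakdown.total


def score_profile(
    profile: EvidenceProfile, scheme: ScoreScheme = DEFAULT_SCHEME
) -> ScoreBreakdown:
    """Award each indicator its scheme points iff its flag is set; sum."""
    awarded = {
        cat: (scheme.points(cat) if profile.flag(cat) else 0)
        for cat in SCORED_CATEGORIES
    }
    return ScoreBreakdown(awarded=awarded, total=sum(awarded.values()), profile=profile)


def score_variants(
    variants: Sequence[Variant],
    catalog: EvidenceCatalog,
    scheme: ScoreScheme = DEFAULT_SCHEME,
) -> list[ScoredVariant]:
    """Annotate and score a variant list; one record per rsID, input order.

    Regional evidence is identical across the alt alleles of one rsID by
    construction; variant-level lookups run per (rsid, alt) and the rsID's
    profile is the union of its alleles' evidence.
    """
    missing = catalog.empty_scored_categories
    by_rsid: dict[str, ScoredVariant] = {}
    order: list[str] = []
    for v in variants:
        profile = evaluate(v, catalog)
        prev = by_rsid.get(v.rsid)
        if prev is None:
            order.append(v.rsid)
            by_rsid[v.rsid] = ScoredVariant(
                variant=v,
                alts=[v.alt],
                profile=profile,
                breakdown=score_profile(profile, scheme),
                categories_missing=list(missing),
            )
        else:
            merged = prev.profile.merged_with(profile)
            prev.alts.append(v.alt)
            prev.profile = merged
            prev.breakdown = score_profile(merged, scheme)
    return [by_rsid[r] for r in order]


def score_histogram(
    breakdowns: Iterable[ScoreBreakdown | int],
    max_score: int = 10,
) -> list[int]:
    """Counts per score value 0..max_score; accepts breakdowns or raw totals."""
    counts = [0] * (max_score + 1)
    for b in breakdowns:
        total = b if isinstance(b, int) else b.total
        if not (0 <= total <= max_score):
            raise ValueError(f"score {total} outside [0, {max_score}]")
        counts[total] += 1
    return counts
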