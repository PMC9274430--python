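"""End-to-end orchestration: parse → select methods → detect → score.

These helpers wire the per-module operations into the two workflows users
actually run: scoring one article, and batch-scoring a corpus into the
record format the aggregation layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from . import affil as affil_mod
from .detect import (
    DetectorRegistry,
    EntityMention,
    default_registry,
    detect_entities,
    link_resources,
    load_resource_catalog,
)
from .jats import Manuscript, parse_article
from .score import ScoreBreakdown, ScoringRules, load_rules, score_mentions

__all__ = ["ScoredPaper", "score_article", "score_manuscript", "score_corpus"]


@dataclass
class ScoredPaper:
    manuscript: Manuscript
    mentions: list[EntityMention]
    breakdown: ScoreBreakdown | None  # None when the article is excluded

    @property
    def excluded(self) -> bool:
        return self.breakdown is None


def score_manuscript(
    manuscript: Manuscript,
    registry: DetectorRegistry | None = None,
    catalog: dict | None = None,
    rules: ScoringRules | None = None,
    mode: str = "rescale",
) -> ScoredPaper:
    """Detect and score one parsed manuscript (no scoring without methods)."""
    if manuscript.methods_text is None:
        return ScoredPaper(manuscript, [], None)
    registry = registry or default_registry()
    catalog = catalog if catalog is not None else load_resource_catalog()
    rules = rules or load_rules()
    text = manuscript.methods_text
    mentions = detect_entities(text, registry)
    mentions = link_resources(mentions, catalog, text)
    breakdown = score_mentions(mentions, rules, mode=mode)
    return ScoredPaper(manuscript, mentions, breakdown)


def score_article(source, **kwargs) -> ScoredPaper:
    """Parse a JATS article (path/string/bytes) and score it."""
    return score_manuscript(parse_article(source), **kwargs)


def score_corpus(
    sources: Iterable,
    institution_registry: affil_mod.Registry | None = None,
    fuzzy_threshold: float = 0.9,
    **kwargs,
) -> list[dict]:
    """Batch-score articles into aggregation-ready records.

    ``sources`` may be JATS paths/bytes or already-parsed ``Manuscript``
    objects. With an institution registry supplied, each paper's affiliation
    strings are split, matched, and credited with multiplicity; countries come
    from the matched registry records. Excluded articles (no methods section)
    yield no record.
    """
    records = []
    for source in sources:
        manuscript = source if isinstance(source, Manuscript) else parse_article(source)
        scored = score_manuscript(manuscript, **kwargs)
        if scored.excluded:
            continue
        institutions: list[str] = []
        countries: list[str] = []
        departments: list[str] = []
        if institution_registry is not None:
            for raw in manuscript.country_strings:
                for m in affil_mod.match_affiliation(
                    raw, institution_registry, threshold=fuzzy_threshold
                ):
                    if m.id is not None:
                        institutions.append(m.id)
                        if m.country:
                            countries.append(m.country)
                    dept = affil_mod.extract_department(m.segment)
                    if dept and m.id is not None:
                        departments.append(f"{dept} | {m.id}")
        records.append(
            {
                "paper_id": manuscript.id,
                "journal": manuscript.journal,
                "year": manuscript.year,
                "abstract": manuscript.abstract,
                "total": scored.breakdown.total,
                "applicable": scored.breakdown.applicable,
                "entity_types": {m.type for m in scored.mentions},
                "institutions": institutions,
                "countries": countries,
                "departments": departments,
                "breakdown": scored.breakdown.to_record(),
            }
        )
    return records
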