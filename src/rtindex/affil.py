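"""Affiliation-string disambiguation against an institution registry.

The workflow: split the raw affiliation string on semicolons, extract an
institution-name candidate from each segment with a keyword-chunk rule, and
look the candidate up in a registry (ROR-style: id, canonical name, aliases,
country). An exact normalized-name hit is a high-confidence match; a unique
best fuzzy hit above a token-set-similarity threshold is low confidence;
otherwise no match. Each segment is processed independently, so one paper can
be credited to several institutions, or several times to one.

Department names are extracted with a separate keyword pattern and are used
(together with the matched top-level institution) as the department identity
for semantic clustering.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Registry",
    "RegistryRecord",
    "InstitutionMatch",
    "load_registry",
    "bundled_registry",
    "split_affiliation",
    "extract_institution_name",
    "match_institution",
    "match_affiliation",
    "evaluate_matching",
    "extract_department",
    "is_uk_affiliation",
    "normalize_name",
    "token_set_similarity",
    "matches_to_csv",
    "INSTITUTION_KEYWORDS",
]

# Keyword list used to pick the institution-name chunk out of a comma-split
# segment. This list is a reconstruction shipped as editable config.
INSTITUTION_KEYWORDS = (
    "university",
    "institute",
    "college",
    "hospital",
    "center",
    "centre",
    "academy",
    "school",
    "clinic",
    "foundation",
    "laboratory",
)

_INSTITUTION_CHUNK_RE = re.compile(
    r"[^,]*\b(?:" + "|".join(INSTITUTION_KEYWORDS) + r")\b[^,]*",
    re.IGNORECASE,
)

# Department extraction pattern: first comma-delimited chunk containing a
# department-style keyword.
DEPARTMENT_RE = re.compile(
    r"[^^,]*(?:department|centre|center|section|division| institute|institution|program|school|museum|group)[^,]*",
    re.IGNORECASE,
)

# Leading junk (numeric affiliation labels etc.) removed from extracted chunks.
_LEADING_JUNK_RE = re.compile(r"^[^A-Z]*")

_UK_MARKERS = ("United Kingdom", "Scotland", "Wales", "England")


@dataclass(frozen=True)
class RegistryRecord:
    id: str
    name: str
    aliases: tuple[str, ...] = ()
    country: str | None = None


@dataclass
class InstitutionMatch:
    """One affiliation segment resolved (or not) to a registry record."""

    segment: str
    id: str | None
    confidence: str  # "high" | "low" | "none"
    country: str | None = None
    name: str | None = None
    score: float | None = None


def normalize_name(name: str) -> str:
    """Casefold, strip diacritics, drop punctuation, collapse whitespace."""
    name = unicodedata.normalize("NFKD", name)
    name = "".join(c for c in name if not unicodedata.combining(c))
    name = re.sub(r"[^\w\s]", " ", name.casefold())
    return " ".join(name.split())


def token_set_similarity(a: str, b: str) -> float:
    """Dice coefficient over normalized unique token sets, in [0, 1]."""
    ta = set(normalize_name(a).split())
    tb = set(normalize_name(b).split())
    if not ta or not tb:
        return 0.0
    return 2.0 * len(ta & tb) / (len(ta) + len(tb))


class Registry:
    """Institution registry with a normalized-name index over names + aliases."""

    def __init__(self, records: Iterable[RegistryRecord]):
        self.records: dict[str, RegistryRecord] = {}
        self.name_index: dict[str, list[str]] = {}
        self.token_index: dict[str, set[str]] = {}
        for rec in records:
            if rec.id in self.records:
                raise ValueError(f"duplicate registry id: {rec.id}")
            self.records[rec.id] = rec
            for name in (rec.name, *rec.aliases):
                key = normalize_name(name)
                if not key:
                    continue
                ids = self.name_index.setdefault(key, [])
                if rec.id not in ids:
                    ids.append(rec.id)
                for tok in key.split():
                    self.token_index.setdefault(tok, set()).add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def candidates(self, candidate: str) -> set[str]:
        """Record ids sharing at least one token with the candidate name."""
        ids: set[str] = set()
        for tok in normalize_name(candidate).split():
            ids |= self.token_index.get(tok, set())
        return ids


def load_registry(source) -> Registry:
    """Load a registry from ROR-schema JSON or minimal CSV.

    CSV columns: ``id,name,aliases,country`` with aliases ``|``-separated.
    JSON: a list of objects with ``id``, ``name``, ``aliases``, ``country``.
    """
    path = Path(source)
    records = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        for item in data:
            records.append(
                RegistryRecord(
                    id=item["id"],
                    name=item["name"],
                    aliases=tuple(item.get("aliases", ())),
                    country=item.get("country"),
                )
            )
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                aliases = tuple(a for a in (row.get("aliases") or "").split("|") if a)
                records.append(
                    RegistryRecord(
                        id=row["id"], name=row["name"],
                        aliases=aliases, country=row.get("country") or None,
                    )
                )
    return Registry(records)


def bundled_registry() -> Registry:
    """The 200-record synthetic fixture registry shipped with the package.

    Generated institutions (ids, names, aliases, countries) for demos and
    tests; no real organization is represented.
    """
    from importlib import resources

    records = []
    path = resources.files("rtindex").joinpath("data", "registry_synthetic_200.csv")
    reader = csv.DictReader(path.read_text(encoding="utf-8").splitlines())
    for row in reader:
        aliases = tuple(a for a in (row.get("aliases") or "").split("|") if a)
        records.append(
            RegistryRecord(
                id=row["id"], name=row["name"],
                aliases=aliases, country=row.get("country") or None,
            )
        )
    return Registry(records)


def split_affiliation(raw: str) -> list[str]:
    """Split on all semicolons; strip whitespace; drop empty segments."""
    return [seg.strip() for seg in raw.split(";") if seg.strip()]


def extract_institution_name(segment: str) -> str | None:
    """The comma-delimited chunk naming an institution, or ``None``.

    The first chunk containing an institution keyword is taken; leading
    non-uppercase junk (numeric labels, stray punctuation) is stripped.
    """
    if not segment:
        return None
    m = _INSTITUTION_CHUNK_RE.search(segment)
    if m is None:
        return None
    chunk = _LEADING_JUNK_RE.sub("", m.group(0), count=1).strip()
    return chunk or None


def match_institution(
    candidate: str | None,
    registry: Registry,
    threshold: float = 0.9,
) -> InstitutionMatch:
    """Resolve one candidate name against the registry.

    Exact normalized hit on a single record → high confidence; exact hit
    shared by several records, or a unique best fuzzy hit at or above the
    threshold → low confidence (ties broken by lexicographically smallest
    id); otherwise no match.
    """
    segment = candidate or ""
    if not candidate:
        return InstitutionMatch(segment=segment, id=None, confidence="none")
    key = normalize_name(candidate)
    exact_ids = registry.name_index.get(key, [])
    if len(exact_ids) == 1:
        rec = registry.records[exact_ids[0]]
        return InstitutionMatch(segment, rec.id, "high", rec.country, rec.name, 1.0)
    if len(exact_ids) > 1:
        rec = registry.records[min(exact_ids)]
        return InstitutionMatch(segment, rec.id, "low", rec.country, rec.name, 1.0)

    best_score = 0.0
    best_ids: list[str] = []
    for rec_id in registry.candidates(candidate):
        rec = registry.records[rec_id]
        score = max(
            token_set_similarity(candidate, name)
            for name in (rec.name, *rec.aliases)
        )
        if score > best_score + 1e-12:
            best_score, best_ids = score, [rec_id]
        elif abs(score - best_score) <= 1e-12:
            best_ids.append(rec_id)
    if best_score >= threshold and best_ids:
        rec = registry.records[min(best_ids)]
        return InstitutionMatch(segment, rec.id, "low", rec.country, rec.name, best_score)
    return InstitutionMatch(segment=segment, id=None, confidence="none")


def match_affiliation(
    raw: str, registry: Registry, threshold: float = 0.9
) -> list[InstitutionMatch]:
    """Full pipeline for one raw affiliation string: split → extract → match."""
    matches = []
    for segment in split_affiliation(raw):
        candidate = extract_institution_name(segment)
        m = match_institution(candidate, registry, threshold=threshold)
        m.segment = segment
        matches.append(m)
    return matches


def evaluate_matching(
    tool_matches: Mapping[str, tuple[str | None, str]],
    curated_matches: Mapping[str, str | None],
) -> dict[str, float]:
    """Accuracy of tool matches against a hand-curated set, per confidence tier.

    ``tool_matches`` maps key → (registry id or None, confidence);
    ``curated_matches`` maps key → registry id or None. Agreement means both
    report the same id, or both report no match. Returns accuracy for
    high-confidence-only predictions and for high+low predictions (in the
    high-only tier, low-confidence predictions count as no-match).
    """
    missing_in_tool = sorted(set(curated_matches) - set(tool_matches))
    missing_in_curated = sorted(set(tool_matches) - set(curated_matches))
    if missing_in_tool or missing_in_curated:
        raise ValueError(
            f"key mismatch; missing in tool: {missing_in_tool}; "
            f"missing in curated: {missing_in_curated}"
        )
    n = len(curated_matches)
    if n == 0:
        raise ValueError("no matches to evaluate")
    agree_high = 0
    agree_all = 0
    for key, truth in curated_matches.items():
        pred_id, confidence = tool_matches[key]
        pred_all = pred_id if confidence in ("high", "low") else None
        pred_high = pred_id if confidence == "high" else None
        if pred_all == truth:
            agree_all += 1
        if pred_high == truth:
            agree_high += 1
    return {"high": agree_high / n, "high_low": agree_all / n}


def extract_department(affiliation: str) -> str | None:
    """First department-style chunk of an affiliation string, or ``None``."""
    m = DEPARTMENT_RE.search(affiliation)
    if m is None:
        return None
    chunk = _LEADING_JUNK_RE.sub("", m.group(0), count=1).strip()
    return chunk or None


def is_uk_affiliation(affiliation: str) -> bool:
    return any(marker in affiliation for marker in _UK_MARKERS)


def matches_to_csv(rows: Sequence[tuple[str, InstitutionMatch, str | None]], path) -> None:
    """Write per-segment match records: paper_id, segment, id, confidence, department."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["paper_id", "segment", "institution_id", "confidence", "department"])
        for paper_id, m, dept in rows:
            writer.writerow([paper_id, m.segment, m.id or "", m.confidence, dept or ""])
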