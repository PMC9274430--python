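"""Rule-based detection of rigor/transparency entities in methods text.

Thirty-one entity types are recognized: rigor criteria (ethics approvals,
randomization, blinding, power analysis, demographics, replication metadata,
cell-line authentication, ...), availability statements and accession-shaped
identifiers for data/code/protocols, key biological resources (antibodies,
organisms, cell lines, software tools, plasmids), and RRID tokens.

Detection is lexicon/regex driven. Each entity type has exactly one detector
registered in a :class:`DetectorRegistry`; detectors are pure functions of the
text, so the full mention list is deterministic. Cue lexicons ship as editable
data files (one per type, ``#`` comments, ``re:`` prefix for regex lines) so
coverage can be extended without code changes — the bundled patterns are this
package's own reconstructions, not a published pattern set. The interface is
pluggable: a trained sequence model can replace any lexicon detector by
registering a callable with the same ``text -> [EntityMention]`` contract.

Span convention: 0-based, half-open character offsets into the supplied text;
``mention.surface == text[start:end]`` always holds. Overlapping mentions of
the same type are merged to the widest covering span; different types may
overlap freely.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ENTITY_TYPES",
    "RESOURCE_TYPES",
    "EntityMention",
    "DetectorRegistry",
    "default_registry",
    "detect_entities",
    "detect_rrids",
    "detect_identifiers",
    "link_resources",
    "load_lexicon",
    "load_resource_catalog",
    "split_sentences",
    "normalize_resource_name",
    "mentions_to_jsonl",
]

#: All recognized entity type names.
ENTITY_TYPES = frozenset(
    {
        "irb",
        "consent",
        "iacuc",
        "field_sample_permit",
        "euthanasia",
        "inclusion_exclusion",
        "attrition",
        "replication_statement",
        "n_replications",
        "replication_type",
        "randomization",
        "blinding",
        "power_analysis",
        "sex",
        "age",
        "weight",
        "cell_line_authentication",
        "cell_line_contamination",
        "protocol_id",
        "code_availability",
        "code_id",
        "data_availability",
        "data_id",
        "antibody",
        "organism",
        "cell_line",
        "software_tool",
        "plasmid",
        "oligonucleotide",
        "statistical_test",
        "rrid",
    }
)

#: Types counted as key biological resources (resource-score denominators).
RESOURCE_TYPES = ("antibody", "organism", "cell_line", "software_tool", "plasmid")

# RRID accession shapes, per registry prefix. The short-accession guard
# (minimum digit counts) rejects malformed tokens such as "AB_0".
_RRID_ACCESSION = (
    r"(?:AB_\d{4,}"
    r"|SCR_\d{3,}"
    r"|CVCL_[A-Z0-9]{4}"
    r"|Addgene_\d{4,}"
    r"|IMSR_[A-Z]{2,10}:\d+"
    r"|MGI:\d{4,}"
    r"|NCBITaxon_\d+"
    r"|RGD_\d{4,})"
)
_RRID_RE = re.compile(r"RRID:\s*(" + _RRID_ACCESSION + r")")

_WORDISH = re.compile(r"\w")

# Sentence splitter: period/question/exclamation followed by whitespace and an
# uppercase letter, guarded against common abbreviations (compared as whole
# trailing tokens, dots stripped).
_ABBREV_GUARD = frozenset(
    {"fig", "figs", "al", "eg", "ie", "vs", "dr", "no", "st", "approx", "ref"}
)
_SENT_BOUNDARY = re.compile(r"[.!?]\s+(?=[A-Z])")


@dataclass
class EntityMention:
    """One detected entity occurrence.

    ``span`` uses 0-based half-open character offsets into the text the
    detector ran on; ``attributes`` carries type-specific extras (bare RRID
    accession, numeric replication count, identifiability flag, ...).
    """

    type: str
    start: int
    end: int
    surface: str
    attributes: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def to_record(self) -> dict:
        return {
            "type": self.type,
            "span": [self.start, self.end],
            "surface": self.surface,
            "attributes": self.attributes,
        }


Detector = Callable[[str], list[EntityMention]]


def _data_path(*parts: str):
    return resources.files("rtindex").joinpath("data", *parts)


def load_lexicon(source) -> list[tuple[str, bool]]:
    """Read a lexicon file into ``(pattern, is_regex)`` entries.

    Blank lines and ``#`` comments are skipped; lines prefixed ``re:`` are raw
    regular expressions, everything else a literal phrase matched
    case-insensitively on word boundaries.
    """
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, (str, Path)) else source.read_text(encoding="utf-8")
    entries: list[tuple[str, bool]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("re:"):
            entries.append((line[3:], True))
        else:
            entries.append((line, False))
    return entries


def _phrase_to_regex(phrase: str) -> str:
    # Literal phrase -> case-insensitive pattern tolerant of flexible
    # whitespace, anchored on word boundaries where the phrase edge is wordish.
    parts = [re.escape(tok) for tok in phrase.split()]
    body = r"\s+".join(parts)
    prefix = r"\b" if _WORDISH.match(phrase[0]) else ""
    suffix = r"\b" if _WORDISH.match(phrase[-1]) else ""
    return f"{prefix}{body}{suffix}"


def _compile_lexicon(entries: Iterable[tuple[str, bool]]) -> list[re.Pattern]:
    compiled = []
    for pattern, is_regex in entries:
        if is_regex:
            compiled.append(re.compile(pattern))
        else:
            compiled.append(re.compile(_phrase_to_regex(pattern), re.IGNORECASE))
    return compiled


def _merge_same_type(mentions: list[EntityMention], text: str) -> list[EntityMention]:
    """Merge overlapping same-type mentions to the widest covering span."""
    if not mentions:
        return []
    mentions = sorted(mentions, key=lambda m: (m.start, -m.end))
    merged: list[EntityMention] = [mentions[0]]
    for m in mentions[1:]:
        last = merged[-1]
        if m.start < last.end:  # overlap
            start, end = last.start, max(last.end, m.end)
            attrs = {**last.attributes, **m.attributes}
            merged[-1] = EntityMention(
                type=last.type, start=start, end=end,
                surface=text[start:end], attributes=attrs,
            )
        else:
            merged.append(m)
    return merged


def _lexicon_detector(entity_type: str, entries: list[tuple[str, bool]]) -> Detector:
    patterns = _compile_lexicon(entries)

    def detect(text: str) -> list[EntityMention]:
        found = []
        for pat in patterns:
            for m in pat.finditer(text):
                if m.start() == m.end():
                    continue
                found.append(
                    EntityMention(entity_type, m.start(), m.end(), m.group(0))
                )
        return _merge_same_type(found, text)

    return detect


_NUMBER_WORDS = {
    "duplicate": 2, "triplicate": 3, "quadruplicate": 4,
    "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
}


def _n_replications_detector(entries: list[tuple[str, bool]]) -> Detector:
    base = _lexicon_detector("n_replications", entries)
    digit_re = re.compile(r"\d+")

    def detect(text: str) -> list[EntityMention]:
        mentions = base(text)
        for m in mentions:
            lowered = m.surface.lower()
            value = None
            dm = digit_re.search(lowered)
            if dm:
                value = int(dm.group(0))
            else:
                for word, n in _NUMBER_WORDS.items():
                    if word in lowered:
                        value = n
                        break
            if value is not None:
                m.attributes["value"] = value
        return mentions

    return detect


def detect_rrids(text: str) -> list[EntityMention]:
    """One mention per RRID token; the bare accession rides in attributes."""
    mentions = []
    for m in _RRID_RE.finditer(text):
        mentions.append(
            EntityMention(
                "rrid", m.start(), m.end(), m.group(0),
                attributes={"accession": m.group(1)},
            )
        )
    return mentions


class DetectorRegistry:
    """Maps every entity type to exactly one detector callable."""

    def __init__(self, detectors: dict[str, Detector]):
        missing = ENTITY_TYPES - set(detectors)
        extra = set(detectors) - ENTITY_TYPES
        if missing:
            raise ValueError(f"no detector registered for: {sorted(missing)}")
        if extra:
            raise ValueError(f"unknown entity types: {sorted(extra)}")
        self.detectors = dict(detectors)

    def register(self, entity_type: str, detector: Detector) -> None:
        """Replace the detector for one type (e.g. with a trained model)."""
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {entity_type}")
        self.detectors[entity_type] = detector

    def types(self) -> frozenset[str]:
        return frozenset(self.detectors)


_DEFAULT_REGISTRY: DetectorRegistry | None = None


def default_registry(lexicon_dir=None) -> DetectorRegistry:
    """Build (and cache) the registry backed by the bundled lexicon files."""
    global _DEFAULT_REGISTRY
    if lexicon_dir is None and _DEFAULT_REGISTRY is not None:
        return _DEFAULT_REGISTRY
    base = _data_path("lexicons") if lexicon_dir is None else Path(lexicon_dir)
    detectors: dict[str, Detector] = {}
    for entity_type in sorted(ENTITY_TYPES - {"rrid"}):
        entries = load_lexicon(base.joinpath(f"{entity_type}.txt"))
        if entity_type == "n_replications":
            detectors[entity_type] = _n_replications_detector(entries)
        else:
            detectors[entity_type] = _lexicon_detector(entity_type, entries)
    detectors["rrid"] = detect_rrids
    registry = DetectorRegistry(detectors)
    if lexicon_dir is None:
        _DEFAULT_REGISTRY = registry
    return registry


def detect_entities(
    text: str,
    registry: DetectorRegistry | None = None,
    failures: list | None = None,
) -> list[EntityMention]:
    """Run every registered detector and return all mentions sorted by start.

    A detector that raises is logged and recorded in ``failures`` (as
    ``(entity_type, exception)``) rather than silently yielding nothing.
    """
    if text is None:
        raise ValueError("text must not be None")
    registry = registry or default_registry()
    mentions: list[EntityMention] = []
    for entity_type in sorted(registry.detectors):
        detector = registry.detectors[entity_type]
        try:
            mentions.extend(detector(text))
        except Exception as exc:  # noqa: BLE001 - detector fault isolation
            logger.warning("detector for %s failed: %s", entity_type, exc)
            if failures is not None:
                failures.append((entity_type, exc))
    mentions.sort(key=lambda m: (m.start, m.end, m.type))
    return mentions


_IDENTIFIER_TYPES = (
    "protocol_id",
    "code_id",
    "data_id",
    "data_availability",
    "code_availability",
)


def detect_identifiers(text: str, registry: DetectorRegistry | None = None) -> list[EntityMention]:
    """Detect only accession-shaped identifiers and availability statements."""
    registry = registry or default_registry()
    mentions: list[EntityMention] = []
    for entity_type in _IDENTIFIER_TYPES:
        mentions.extend(registry.detectors[entity_type](text))
    mentions.sort(key=lambda m: (m.start, m.end, m.type))
    return mentions


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans: ``. `` + uppercase, with abbreviation guard."""
    spans = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        cut = m.start() + 1  # just past the punctuation
        head = text[start:m.start()].rstrip().lower()
        last_token = head.split()[-1].replace(".", "") if head.split() else ""
        if last_token in _ABBREV_GUARD:
            continue
        spans.append((start, cut))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def normalize_resource_name(name: str) -> str:
    """Casefold, strip diacritics and punctuation, collapse whitespace."""
    name = unicodedata.normalize("NFKD", name)
    name = "".join(c for c in name if not unicodedata.combining(c))
    name = re.sub(r"[^\w\s]", " ", name.casefold())
    return " ".join(name.split())


def load_resource_catalog(source=None) -> dict[str, str]:
    """Load the name→RRID suggestion catalog, keys normalized."""
    if source is None:
        raw = json.loads(_data_path("resource_catalog.json").read_text(encoding="utf-8"))
    else:
        raw = json.loads(Path(source).read_text(encoding="utf-8"))
    entries = raw["entries"] if "entries" in raw else raw
    return {normalize_resource_name(k): v for k, v in entries.items()}


def link_resources(
    mentions: Sequence[EntityMention],
    catalog: dict[str, str] | None = None,
    text: str | None = None,
) -> list[EntityMention]:
    """Flag resource mentions as uniquely identifiable.

    A resource mention (antibody/organism/cell line/software tool/plasmid) is
    identifiable iff an RRID mention occurs in the same sentence, or its
    normalized surface has a catalog entry (an "RRID suggestion"). Returns the
    mention list with ``identifiable`` set in each resource mention's
    attributes.
    """
    if catalog is None:
        catalog = load_resource_catalog()
    rrid_spans = [(m.start, m.end, m) for m in mentions if m.type == "rrid"]
    sentences = split_sentences(text) if text is not None else []

    def same_sentence(a: EntityMention, b: EntityMention) -> bool:
        for s, e in sentences:
            if s <= a.start < e and s <= b.start < e:
                return True
        return False

    out = []
    for m in mentions:
        if m.type not in RESOURCE_TYPES:
            out.append(m)
            continue
        identifiable = False
        rrid = None
        key = normalize_resource_name(m.surface)
        if key in catalog:
            identifiable = True
            rrid = catalog[key]
        if not identifiable:
            for _, _, rm in rrid_spans:
                if (text is not None and same_sentence(m, rm)) or (
                    text is None and abs(rm.start - m.end) <= 80
                ):
                    identifiable = True
                    rrid = rm.attributes.get("accession")
                    break
        m.attributes["identifiable"] = identifiable
        if rrid is not None:
            m.attributes.setdefault("rrid", rrid)
        out.append(m)
    return out


def mentions_to_jsonl(mentions: Sequence[EntityMention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps(m.to_record()) + "\n")
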