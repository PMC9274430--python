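"""Conditional rigor + resource scoring of one manuscript (10-point scale).

The rigor-adherence component compares the number of criteria *groupings*
detected against the number the conditional logic expects. Groupings, their
member entity types, their trigger relations ("if this grouping is detected,
what is expected?"), and which score they feed are all data — the engine reads
``data/scoring_rules.json`` and contains no hard-coded grouping logic.

Key behaviors of the found/expected comparison:

* ``random``, ``blinding`` and ``power`` are always expected.
* Detecting a grouping adds its triggered groupings to the expected set
  (e.g. an ethics approval triggers group selection, sex, demographics,
  randomization, blinding and power — six expectations).
* Never-expected groupings (field permits, euthanasia, replication, cell
  lines) still count as *found* when detected: reporting them is rewarded,
  they are just never demanded.
* The found/expected ratio is capped at 1, so rigor points lie in [0, 5].

The resource-identifiability component is the fraction of detected key
biological resources (antibodies, organisms, cell lines, software tools,
plasmids) that are uniquely identifiable (inline RRID or catalog suggestion),
scaled to 5 points.

A paper whose only detections are non-scoring types (availability statements,
identifiers, statistical tests, oligonucleotides) — or that has no detections
at all — is *not applicable*: total 0, excluded from every downstream mean.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .detect import EntityMention

__all__ = [
    "Grouping",
    "ScoringRules",
    "ScoreBreakdown",
    "load_rules",
    "detected_groupings",
    "expected_groupings",
    "rigor_score",
    "resource_score",
    "total_score",
    "score_mentions",
    "round_half_up",
    "breakdowns_to_csv",
]


@dataclass(frozen=True)
class Grouping:
    name: str
    members: frozenset[str]
    expects: frozenset[str]
    expected_when: str | frozenset[str]  # "always" | "never" | trigger set
    affects: str  # "rigor" | "resource" | "none"


class ScoringRules:
    """The machine-readable conditional-scoring table."""

    def __init__(self, groupings: Sequence[Grouping], always_expected, never_expected, resource_types):
        self.groupings = {g.name: g for g in groupings}
        self.always_expected = frozenset(always_expected)
        self.never_expected = frozenset(never_expected)
        self.resource_types = tuple(resource_types)
        self.type_to_groupings: dict[str, set[str]] = {}
        for g in groupings:
            for t in g.members:
                self.type_to_groupings.setdefault(t, set()).add(g.name)

    def scoring_groupings(self) -> frozenset[str]:
        """Groupings that feed the rigor score."""
        return frozenset(n for n, g in self.groupings.items() if g.affects == "rigor")


_DEFAULT_RULES: ScoringRules | None = None


def load_rules(path=None) -> ScoringRules:
    """Load scoring rules; defaults to the bundled rules file (cached)."""
    global _DEFAULT_RULES
    if path is None and _DEFAULT_RULES is not None:
        return _DEFAULT_RULES
    if path is None:
        raw = json.loads(
            resources.files("rtindex").joinpath("data", "scoring_rules.json").read_text(encoding="utf-8")
        )
    else:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    groupings = []
    for g in raw["groupings"]:
        ew = g["expected_when"]
        groupings.append(
            Grouping(
                name=g["name"],
                members=frozenset(g["members"]),
                expects=frozenset(g["expects"]),
                expected_when=ew if isinstance(ew, str) else frozenset(ew),
                affects=g["affects"],
            )
        )
    rules = ScoringRules(
        groupings, raw["always_expected"], raw["never_expected"], raw["resource_types"]
    )
    if path is None:
        _DEFAULT_RULES = rules
    return rules


@dataclass
class ScoreBreakdown:
    """Per-paper scoring result."""

    detected_groupings: frozenset[str]
    expected_groupings: frozenset[str]
    found_count: int
    expected_count: int
    rigor_fraction: float
    rigor_points: float
    resources_total: int
    resources_identifiable: int
    resource_points: float
    total: float
    applicable: bool
    rigor_applicable: bool = True
    resource_applicable: bool = True
    non_scoring_groupings: frozenset[str] = field(default_factory=frozenset)

    def display_total(self) -> int:
        """Integer display scale (half-up rounding)."""
        return round_half_up(self.total)

    def display_rigor(self) -> int:
        return round_half_up(self.rigor_points)

    def display_resource(self) -> int:
        return round_half_up(self.resource_points)

    def to_record(self) -> dict:
        return {
            "detected_groupings": sorted(self.detected_groupings),
            "expected_groupings": sorted(self.expected_groupings),
            "found_count": self.found_count,
            "expected_count": self.expected_count,
            "rigor_fraction": self.rigor_fraction,
            "rigor_points": self.rigor_points,
            "resources_total": self.resources_total,
            "resources_identifiable": self.resources_identifiable,
            "resource_points": self.resource_points,
            "total": self.total,
            "applicable": self.applicable,
            "rigor_applicable": self.rigor_applicable,
            "resource_applicable": self.resource_applicable,
            "non_scoring_groupings": sorted(self.non_scoring_groupings),
        }


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def detected_groupings(
    mentions: Iterable[EntityMention], rules: ScoringRules | None = None
) -> frozenset[str]:
    """Groupings with at least one member-type mention (scoring or not)."""
    rules = rules or load_rules()
    names: set[str] = set()
    for m in mentions:
        names |= rules.type_to_groupings.get(m.type, set())
    return frozenset(names)


def expected_groupings(
    detected: Iterable[str], rules: ScoringRules | None = None
) -> frozenset[str]:
    """The expected set given the detected groupings.

    Always-expected groupings plus everything triggered by a detected
    grouping; never-expected groupings are excluded even when detected.
    """
    rules = rules or load_rules()
    expected = set(rules.always_expected)
    for name in detected:
        g = rules.groupings.get(name)
        if g is not None:
            expected |= g.expects
    return frozenset(expected - rules.never_expected)


def rigor_score(
    detected: Iterable[str],
    expected: Iterable[str],
    rules: ScoringRules | None = None,
) -> tuple[int, int, float]:
    """(found_count, expected_count, rigor_points).

    Found counts every detected rigor-affecting grouping, whether or not it
    is itself in the expected set; the ratio is capped at 1 and scaled to 5.
    """
    rules = rules or load_rules()
    detected = frozenset(detected)
    expected = frozenset(expected)
    found = len(detected & rules.scoring_groupings())
    expected_count = len(expected)
    if expected_count == 0:
        return found, 0, 0.0
    points = 5.0 * min(found / expected_count, 1.0)
    return found, expected_count, points


def resource_score(
    mentions: Iterable[EntityMention], rules: ScoringRules | None = None
) -> tuple[int, int, float]:
    """(resources_total, resources_identifiable, resource_points).

    Counts mentions of the key-resource types; identifiability comes from the
    ``identifiable`` attribute set by :func:`rtindex.detect.link_resources`.
    Zero detected resources ⇒ 0 points and component inapplicable.
    """
    rules = rules or load_rules()
    total = 0
    identifiable = 0
    for m in mentions:
        if m.type in rules.resource_types:
            total += 1
            if m.attributes.get("identifiable"):
                identifiable += 1
    if total == 0:
        return 0, 0, 0.0
    return total, identifiable, 5.0 * identifiable / total


def total_score(
    rigor_points: float,
    resource_points: float,
    rigor_applicable: bool,
    resource_applicable: bool,
    mode: str = "rescale",
) -> tuple[float, bool]:
    """Combine the two 5-point components into the 10-point total.

    ``rescale`` (default): when exactly one component is applicable, it is
    rescaled to the full 10-point range, so resource-free study designs are
    not structurally penalized. ``sum`` adds the raw points regardless.
    """
    if not rigor_applicable and not resource_applicable:
        return 0.0, False
    if mode == "sum":
        return rigor_points + resource_points, True
    if mode != "rescale":
        raise ValueError(f"unknown combination mode: {mode}")
    if rigor_applicable and resource_applicable:
        return rigor_points + resource_points, True
    if rigor_applicable:
        return 2.0 * rigor_points, True
    return 2.0 * resource_points, True


def score_mentions(
    mentions: Sequence[EntityMention],
    rules: ScoringRules | None = None,
    mode: str = "rescale",
) -> ScoreBreakdown:
    """Score one paper's mention list end to end."""
    rules = rules or load_rules()
    detected = detected_groupings(mentions, rules)
    expected = expected_groupings(detected, rules)
    found, expected_count, rigor_pts = rigor_score(detected, expected, rules)
    res_total, res_ident, res_pts = resource_score(mentions, rules)

    rigor_applicable = found > 0
    resource_applicable = res_total > 0
    total, applicable = total_score(
        rigor_pts, res_pts, rigor_applicable, resource_applicable, mode=mode
    )
    non_scoring = frozenset(
        n for n in detected if rules.groupings[n].affects == "none"
    )
    return ScoreBreakdown(
        detected_groupings=detected,
        expected_groupings=expected,
        found_count=found,
        expected_count=expected_count,
        rigor_fraction=(min(found / expected_count, 1.0) if expected_count else 0.0),
        rigor_points=rigor_pts if applicable else 0.0,
        resources_total=res_total,
        resources_identifiable=res_ident,
        resource_points=res_pts if applicable else 0.0,
        total=total,
        applicable=applicable,
        rigor_applicable=rigor_applicable,
        resource_applicable=resource_applicable,
        non_scoring_groupings=non_scoring,
    )


def breakdowns_to_csv(records: Sequence[tuple[str, ScoreBreakdown]], path) -> None:
    """One-line-per-paper CSV summary (id, rigor, resource, total, applicable)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "rigor", "resource", "total", "applicable"])
        for paper_id, b in records:
            writer.writerow(
                [paper_id, f"{b.rigor_points:.4f}", f"{b.resource_points:.4f}",
                 f"{b.total:.4f}", str(b.applicable).lower()]
            )
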