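"""Synthetic corpora with known ground truth.

Everything the pipeline consumes can be generated here deterministically from
a seed: JATS articles whose methods sections contain entities planted at
configurable rates (rendered with the detectors' own cue phrases, so a
zero-noise corpus is recoverable exactly), affiliation strings built from a
synthetic institution registry with controllable character-level noise, and
abstracts drawn from configurable topic vocabularies.

Ground truth ships with every corpus: the planted entity types per paper, the
true institution ids, the topic label, and the expected score breakdown. The
expected breakdown is computed by :func:`oracle_breakdown`, a deliberately
naive straight-line transcription of the conditional-scoring table that
shares no code with :mod:`rtindex.score` — the two implementations can
disagree meaningfully, which is the point.

A paraphrase tier exists to *measure* lexicon recall: with
``paraphrase_rate > 0`` some planted entities are rendered with wordings the
bundled lexicons do not cover. Paraphrased plants are recorded separately in
the ground truth and excluded from exact-recovery assertions.

What this generator does not emulate: real scientific prose, journal-specific
XML quirks, table-borne reagent lists, or correlated reporting behavior
(entities are planted independently). Passing tests on synthetic corpora
demonstrate pipeline correctness, not real-world detector recall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .detect import load_resource_catalog, normalize_resource_name
from .jats import Manuscript, manuscript_to_jats

__all__ = [
    "CorpusSpec",
    "PaperTruth",
    "GroundTruth",
    "generate_corpus",
    "generate_registry",
    "registry_to_csv",
    "oracle_breakdown",
    "DEFAULT_PLANT_RATES",
    "PLANT_SENTENCES",
    "PARAPHRASE_SENTENCES",
]

# ----------------------------------------------------------------------------
# cue-phrase rendering
#
# One sentence per entity type, each containing exactly one cue phrase from
# that type's bundled lexicon and nothing that fires any other detector
# (enforced by the planted-exclusivity test).
PLANT_SENTENCES = {
    "irb": "The study protocol was approved by the Institutional Review Board of the host organization.",
    "consent": "Written informed consent was obtained from every participant.",
    "iacuc": "All procedures were approved by the Institutional Animal Care and Use Committee.",
    "field_sample_permit": "A field sample permit was obtained from the regional authority.",
    "euthanasia": "Animals were euthanized at the conclusion of the experiment.",
    "inclusion_exclusion": "Participants met predefined inclusion criteria before enrollment.",
    "attrition": "Two participants were lost to follow-up during the trial.",
    "replication_statement": "Key experiments were replicated in separate sessions.",
    "n_replications": "Each assay was performed in triplicate.",
    "replication_type": "We analyzed biological replicates for every condition.",
    "randomization": "Subjects were randomly assigned to treatment groups.",
    "blinding": "Investigators were blinded to group allocation throughout.",
    "power_analysis": "A power analysis determined the required group size.",
    "sex": "Both male and female subjects were enrolled.",
    "age": "Subjects were 8 weeks old at the start of the experiment.",
    "weight": "Animals weighing 200 to 250 g were used.",
    "cell_line_authentication": "Cultures were authenticated by STR profiling before use.",
    "cell_line_contamination": "Cultures tested negative for mycoplasma throughout the study.",
    "protocol_id": "The step-by-step protocol is archived at protocols.io/view/synthetic-protocol-1.",
    "code_availability": "Analysis code is available from the corresponding author.",
    "code_id": "Custom scripts are archived at https://github.com/synthlab/analysis-pipeline.",
    "data_availability": "All underlying data are available upon request.",
    "data_id": "Sequencing reads were uploaded to GEO under accession GSE49712.",
    "oligonucleotide": "The siRNA targeting sequences were obtained commercially.",
    "statistical_test": "Group differences were assessed with one-way ANOVA.",
}

# Wordings the bundled lexicons deliberately do not cover; used to measure
# (never assert) recall, mirroring the curator-vs-classifier gap.
PARAPHRASE_SENTENCES = {
    "randomization": "Group membership was decided by a coin toss.",
    "blinding": "The rater did not know which condition each subject belonged to.",
    "power_analysis": "We computed how many subjects would suffice before starting.",
    "attrition": "Several enrollees stopped participating midway.",
    "data_availability": "Readers may ask us for the underlying measurements.",
    "sex": "Half the cohort was of each gender.",
}

# Sentences guaranteed not to fire any detector; used as connective tissue.
_FILLER_SENTENCES = (
    "The apparatus was assembled following the manufacturer's instructions.",
    "Buffer solutions were prepared fresh each morning.",
    "Incubation steps were carried out at room temperature.",
    "Imaging sessions took place between 9 AM and noon.",
    "Reagent lots were recorded in the notebook.",
    "Samples were stored at -80 degrees until processing.",
)

# Resource name pools: (rendered name, sentence template). Catalog membership
# is looked up at generation time, so identifiability ground truth follows
# whatever catalog the pipeline will use.
_RESOURCE_POOLS = {
    "antibody": (
        ("anti-synaptophysin antibody", "Sections were stained with a rabbit {name}{rrid}."),
        ("anti-GFAP antibody", "Blots were probed with a mouse {name}{rrid}."),
    ),
    "organism": (
        ("C57BL/6J mice", "Experiments used adult {name}{rrid} housed under standard conditions."),
        ("Sprague-Dawley rats", "Adult {name}{rrid} were obtained from a commercial supplier."),
        ("zebrafish", "Larval {name}{rrid} were raised at 28 degrees."),
    ),
    "cell_line": (
        ("HeLa cells", "Cultured {name}{rrid} were maintained in DMEM."),
        ("U2OS cells", "We grew {name}{rrid} in supplemented McCoy medium."),
        ("CHO cells", "Suspension {name}{rrid} were passaged twice weekly."),
    ),
    "software_tool": (
        ("ImageJ", "Images were quantified with {name}{rrid}."),
        ("GraphPad Prism", "Plots were generated in {name}{rrid}."),
        ("MATLAB", "Signals were processed in {name}{rrid}."),
        ("SPSS", "Models were fitted in {name}{rrid}."),
    ),
    "plasmid": (
        ("pcDNA3.1", "Cells were transfected with the {name}{rrid} construct."),
        ("psPAX2", "Lentivirus was packaged with {name}{rrid}."),
    ),
}

# RRID accession shapes rendered per resource type.
_RRID_SHAPES = {
    "antibody": ("AB_", 7),
    "organism": ("IMSR_JAX:", 6),
    "cell_line": ("CVCL_", 4),
    "software_tool": ("SCR_", 6),
    "plasmid": ("Addgene_", 5),
}

#: Default plant rates: per-paper probabilities of each entity type. Where the
#: literature-wide addressment proportions reported for recent years are
#: known (randomization ~31%, blinding ~9%, power ~8%, data ~17%, code ~3%),
#: those are used directly; the remainder are set to magnitudes typical of
#: biomedical methods sections.
DEFAULT_PLANT_RATES = {
    "irb": 0.30,
    "consent": 0.25,
    "iacuc": 0.20,
    "field_sample_permit": 0.02,
    "euthanasia": 0.10,
    "inclusion_exclusion": 0.20,
    "attrition": 0.08,
    "replication_statement": 0.20,
    "n_replications": 0.15,
    "replication_type": 0.06,
    "randomization": 0.31,
    "blinding": 0.09,
    "power_analysis": 0.08,
    "sex": 0.30,
    "age": 0.35,
    "weight": 0.15,
    "cell_line_authentication": 0.03,
    "cell_line_contamination": 0.03,
    "protocol_id": 0.01,
    "code_availability": 0.03,
    "code_id": 0.01,
    "data_availability": 0.15,
    "data_id": 0.05,
    "oligonucleotide": 0.15,
    "statistical_test": 0.50,
    "antibody": 0.30,
    "organism": 0.40,
    "cell_line": 0.25,
    "software_tool": 0.50,
    "plasmid": 0.10,
}

_DEFAULT_TOPICS = (
    (
        "neuron synapse cortex hippocampus dendrite axon glia plasticity "
        "electrophysiology spike receptor channel memory behavior circuit"
    ).split(),
    (
        "lymphocyte cytokine antigen inflammation macrophage innate adaptive "
        "vaccine pathogen infection antibody-response tolerance thymus spleen"
    ).split(),
    (
        "genome transcriptome sequencing variant annotation pipeline alignment "
        "expression regulatory chromatin motif assembly phylogeny mutation"
    ).split(),
)

_COUNTRIES = (
    "United States", "United Kingdom", "Germany", "France", "Japan", "China",
    "Norway", "Ethiopia", "Brazil", "Canada", "Australia", "Netherlands",
)

_PLACE_HEADS = (
    "Ar", "Bel", "Cor", "Dun", "El", "Fen", "Gar", "Hol", "Is", "Jor", "Kel",
    "Lor", "Mar", "Nor", "Or", "Pel", "Quin", "Ros", "Sel", "Tor", "Ul",
    "Ver", "Wes", "Xan", "Yor", "Zel",
)
_PLACE_MIDS = ("an", "en", "in", "on", "ar", "or", "el", "un")
_PLACE_TAILS = ("dale", "ford", "holm", "mont", "ville", "wick", "stad", "burg", "field", "haven")

_NAME_PATTERNS = (
    "University of {place}",
    "{place} Institute of Science",
    "{place} Medical College",
    "{place} Central Hospital",
    "{place} Academy of Sciences",
)

_DEPARTMENT_FIELDS = (
    "Department of Neuroscience",
    "Department of Immunology",
    "Department of Computational Biology",
    "Department of Physiology",
    "Department of Pharmacology",
)


@dataclass
class CorpusSpec:
    """Parameters of one synthetic corpus; ``seed`` is mandatory."""

    seed: int
    n_papers: int = 500
    year_range: tuple[int, int] = (2016, 2020)
    entity_plant_rates: dict = dc_field(default_factory=lambda: dict(DEFAULT_PLANT_RATES))
    rrid_rate: float = 0.30
    n_institutions: int = 50
    affiliation_noise: float = 0.0
    topic_vocabularies: Sequence[Sequence[str]] = _DEFAULT_TOPICS
    n_journals: int = 4
    paraphrase_rate: float = 0.0

    def validate(self) -> None:
        if self.n_papers < 1:
            raise ValueError("n_papers must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")
        for t, p in self.entity_plant_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"plant rate for {t} outside [0, 1]")
            if t not in PLANT_SENTENCES and t not in _RESOURCE_POOLS:
                raise ValueError(f"no plant template for entity type {t!r}")
        for p, name in ((self.rrid_rate, "rrid_rate"), (self.affiliation_noise, "affiliation_noise"),
                        (self.paraphrase_rate, "paraphrase_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_institutions < 1 or self.n_journals < 1:
            raise ValueError("need at least one institution and one journal")
        if not self.topic_vocabularies:
            raise ValueError("at least one topic vocabulary required")


@dataclass
class PaperTruth:
    """Ground truth for one generated paper."""

    paper_id: str
    journal: str
    year: int
    planted_types: frozenset[str]
    paraphrased_types: frozenset[str]
    resources: list[dict]  # {type, name, rrid, identifiable}
    institution_ids: list[str]  # with multiplicity
    countries: list[str]
    topic: int
    breakdown: dict  # oracle-computed expected score breakdown


@dataclass
class GroundTruth:
    papers: dict[str, PaperTruth]

    def to_json(self) -> str:
        return json.dumps(
            {
                pid: {
                    "journal": t.journal,
                    "year": t.year,
                    "planted_types": sorted(t.planted_types),
                    "paraphrased_types": sorted(t.paraphrased_types),
                    "resources": t.resources,
                    "institution_ids": t.institution_ids,
                    "countries": t.countries,
                    "topic": t.topic,
                    "breakdown": t.breakdown,
                }
                for pid, t in self.papers.items()
            },
            indent=1,
        )


# ----------------------------------------------------------------------------
# independent oracle scorer (straight-line; shares nothing with rtindex.score)

_ORACLE_RIGOR_GROUPINGS = (
    "ethics1", "ethics2", "euthanasia", "group_selection", "sex",
    "demographics", "random", "blinding", "power", "replication",
    "cell_line_auth", "cell_lines",
)


def oracle_breakdown(planted_types, resources) -> dict:
    """Expected score for a set of planted types, written longhand.

    ``resources`` is a sequence of dicts with an ``identifiable`` flag.
    """
    t = set(planted_types)
    d = set()
    if t & {"iacuc", "irb", "consent"}:
        d.add("ethics1")
    if "field_sample_permit" in t:
        d.add("ethics2")
    if "euthanasia" in t:
        d.add("euthanasia")
    if t & {"inclusion_exclusion", "attrition"}:
        d.add("group_selection")
    if "sex" in t:
        d.add("sex")
    if t & {"age", "weight"}:
        d.add("demographics")
    if "randomization" in t:
        d.add("random")
    if "blinding" in t:
        d.add("blinding")
    if "power_analysis" in t:
        d.add("power")
    if t & {"replication_statement", "n_replications", "replication_type"}:
        d.add("replication")
    if t & {"cell_line_authentication", "cell_line_contamination"}:
        d.add("cell_line_auth")
    if "cell_line" in t:
        d.add("cell_lines")
    if t & {"data_availability", "data_id", "code_availability", "code_id", "protocol_id"}:
        d.add("methods_materials_availability")
    if t & {"antibody", "organism", "plasmid", "software_tool"}:
        d.add("other_resources")
    if t & {"oligonucleotide", "statistical_test"}:
        d.add("misc")

    expected = {"random", "blinding", "power"}
    if "ethics1" in d:
        expected |= {"group_selection", "sex", "demographics"}
    if "euthanasia" in d:
        expected |= {"ethics1", "group_selection", "sex", "demographics"}
    if "demographics" in d:
        expected |= {"sex"}
    if "cell_line_auth" in d:
        expected |= {"sex"}
    if "cell_lines" in d:
        expected |= {"cell_line_auth"}

    found = sum(1 for g in _ORACLE_RIGOR_GROUPINGS if g in d)
    expected_count = len(expected)
    rigor_points = 5.0 * min(found / expected_count, 1.0) if expected_count else 0.0

    res_total = len(resources)
    res_ident = sum(1 for r in resources if r["identifiable"])
    resource_points = 5.0 * res_ident / res_total if res_total else 0.0

    rigor_applicable = found > 0
    resource_applicable = res_total > 0
    if rigor_applicable and resource_applicable:
        total, applicable = rigor_points + resource_points, True
    elif rigor_applicable:
        total, applicable = 2.0 * rigor_points, True
    elif resource_applicable:
        total, applicable = 2.0 * resource_points, True
    else:
        total, applicable = 0.0, False

    return {
        "detected_groupings": sorted(d),
        "expected_groupings": sorted(expected),
        "found_count": found,
        "expected_count": expected_count,
        "rigor_points": rigor_points if applicable else 0.0,
        "resources_total": res_total,
        "resources_identifiable": res_ident,
        "resource_points": resource_points if applicable else 0.0,
        "total": total,
        "applicable": applicable,
    }


# ----------------------------------------------------------------------------
# registry generation


def generate_registry(n: int, seed: int = 0) -> list[dict]:
    """``n`` synthetic institutions with unique ids, names, aliases, countries."""
    if n < 1:
        raise ValueError("n must be >= 1")
    places = [
        h + m + t for h in _PLACE_HEADS for m in _PLACE_MIDS for t in _PLACE_TAILS
    ]
    if n > len(places):
        raise ValueError(f"at most {len(places)} institutions supported")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(places))
    records = []
    for i in range(n):
        place = places[order[i]]
        name = _NAME_PATTERNS[i % len(_NAME_PATTERNS)].format(place=place)
        # alias candidates reuse the unique place token, so they can never
        # collide with another record's canonical name
        candidates = [f"The {name}", f"{place} Campus {name.split()[0]}"]
        n_alias = int(rng.integers(0, 4))
        aliases = candidates[: min(n_alias, len(candidates))]
        records.append(
            {
                "id": f"INST{i:05d}",
                "name": name,
                "aliases": aliases,
                "country": _COUNTRIES[int(rng.integers(0, len(_COUNTRIES)))],
            }
        )
    return records


def registry_to_csv(records: Sequence[dict], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "aliases", "country"])
        for r in records:
            writer.writerow([r["id"], r["name"], "|".join(r["aliases"]), r["country"]])


# ----------------------------------------------------------------------------
# corpus generation


def _noisy(name: str, noise: float, rng) -> str:
    if noise <= 0:
        return name
    chars = list(name)
    for i, c in enumerate(chars):
        if c.isalpha() and rng.random() < noise:
            chars[i] = chr(ord("a") + int(rng.integers(0, 26)))
    return "".join(chars)


def _render_rrid(resource_type: str, rng) -> str:
    prefix, digits = _RRID_SHAPES[resource_type]
    if resource_type == "cell_line":
        alphabet = "0123456789ABCDEFGHJKMNPQRSTUVWXYZ"
        acc = "".join(alphabet[int(rng.integers(0, len(alphabet)))] for _ in range(digits))
    else:
        acc = "".join(str(int(rng.integers(0, 10))) for _ in range(digits))
        acc = "1" + acc[1:]  # keep the minimum-length shape safe
    return prefix + acc


def generate_corpus(spec: CorpusSpec, out_dir=None, registry=None):
    """Generate a corpus and its ground truth.

    Returns ``(articles, truth, registry)`` where ``articles`` is a list of
    ``(paper_id, xml_bytes)`` in generation order. With ``out_dir`` set, the
    JATS files, the registry (JSON) and the ground truth (JSON) are also
    written there. Deterministic: the same spec yields byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if registry is None:
        registry = generate_registry(spec.n_institutions, seed=spec.seed + 1)
    catalog = load_resource_catalog()

    journals = [f"Journal of Synthetic Research {chr(65 + k)}" for k in range(spec.n_journals)]
    years = list(range(spec.year_range[0], spec.year_range[1] + 1))
    rate_items = sorted(spec.entity_plant_rates.items())

    articles: list[tuple[str, bytes]] = []
    truths: dict[str, PaperTruth] = {}

    for i in range(spec.n_papers):
        paper_id = f"SYN{i:06d}"
        journal = journals[int(rng.integers(0, len(journals)))]
        year = years[int(rng.integers(0, len(years)))]

        planted: set[str] = set()
        paraphrased: set[str] = set()
        resources: list[dict] = []
        sentences: list[str] = []

        for entity_type, rate in rate_items:
            if rng.random() >= rate:
                continue
            if entity_type in _RESOURCE_POOLS:
                pool = _RESOURCE_POOLS[entity_type]
                name, template = pool[int(rng.integers(0, len(pool)))]
                has_rrid = rng.random() < spec.rrid_rate
                rrid = _render_rrid(entity_type, rng) if has_rrid else None
                in_catalog = normalize_resource_name(name) in catalog
                resources.append(
                    {
                        "type": entity_type,
                        "name": name,
                        "rrid": rrid,
                        "identifiable": bool(has_rrid or in_catalog),
                    }
                )
                rrid_part = f" (RRID:{rrid})" if rrid else ""
                sentences.append(template.format(name=name, rrid=rrid_part))
                planted.add(entity_type)
            else:
                use_paraphrase = (
                    spec.paraphrase_rate > 0
                    and entity_type in PARAPHRASE_SENTENCES
                    and rng.random() < spec.paraphrase_rate
                )
                if use_paraphrase:
                    sentences.append(PARAPHRASE_SENTENCES[entity_type])
                    paraphrased.add(entity_type)
                else:
                    sentences.append(PLANT_SENTENCES[entity_type])
                planted.add(entity_type)

        # interleave inert filler so documents are not bare cue lists
        body: list[str] = [_FILLER_SENTENCES[i % len(_FILLER_SENTENCES)]]
        for j, s in enumerate(sentences):
            body.append(s)
            if j % 3 == 2:
                body.append(_FILLER_SENTENCES[(i + j) % len(_FILLER_SENTENCES)])
        methods_text = " ".join(body)

        topic = int(rng.integers(0, len(spec.topic_vocabularies)))
        vocab = list(spec.topic_vocabularies[topic])
        abstract_words = [vocab[int(rng.integers(0, len(vocab)))] for _ in range(40)]
        abstract = "We study " + " ".join(abstract_words) + "."

        n_affils = int(rng.integers(1, 3))
        inst_ids = [registry[int(rng.integers(0, len(registry)))]["id"] for _ in range(n_affils)]
        segments = []
        countries = []
        for inst_id in inst_ids:
            rec = next(r for r in registry if r["id"] == inst_id)
            dept = _DEPARTMENT_FIELDS[int(rng.integers(0, len(_DEPARTMENT_FIELDS)))]
            noisy_name = _noisy(rec["name"], spec.affiliation_noise, rng)
            segments.append(f"{dept}, {noisy_name}, {rec['country']}")
            countries.append(rec["country"])
        affiliation = "; ".join(segments)

        manuscript = Manuscript(
            id=paper_id,
            journal=journal,
            year=year,
            country_strings=[affiliation],
            abstract=abstract,
            methods_text=methods_text,
            publication_types=["research-article"],
        )
        xml = manuscript_to_jats(manuscript)
        articles.append((paper_id, xml))

        exact_types = planted - paraphrased
        truths[paper_id] = PaperTruth(
            paper_id=paper_id,
            journal=journal,
            year=year,
            planted_types=frozenset(planted),
            paraphrased_types=frozenset(paraphrased),
            resources=resources,
            institution_ids=inst_ids,
            countries=countries,
            topic=topic,
            breakdown=oracle_breakdown(exact_types, resources),
        )

    truth = GroundTruth(papers=truths)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for paper_id, xml in articles:
            (out / f"{paper_id}.xml").write_bytes(xml)
        (out / "registry.json").write_text(json.dumps(registry, indent=1), encoding="utf-8")
        (out / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")

    return articles, truth, registry
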