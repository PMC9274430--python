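# Methods

This note documents the models and procedures implemented in `rtindex`, the
choices made where the design was genuinely open, and what the synthetic
test corpora do and do not demonstrate.

## Text units

Articles are read from JATS XML (the PMC-OAI dialect). Only the
materials-and-methods section is searched for entities: a `<sec>` is taken
as methods when its `sec-type` is one of `methods`, `materials|methods`,
`materials-and-methods`, or its title matches (case-insensitively) one of
*methods*, *materials and methods*, *methods and materials*, *experimental
procedures*, *star methods*. JATS does not constrain `sec-type` values, so
this lexicon is a package choice and is editable
(`rtindex.jats.METHODS_SEC_TYPES` / `METHODS_TITLES`). Paragraphs of the
methods subtree are concatenated in document order; the cell text of tables
nested inside methods is appended after the prose, using structural
`<table-wrap>`/`<tr>`/`<td>` parsing. PDFs and supplementary files are
invisible by design. An article without a methods section is excluded from
scoring entirely (a deliberate conservatism: criteria reported only in
results or dedicated availability sections are missed — see Limitations).

Spans are 0-based, half-open character offsets into the selected methods
text; every mention satisfies `surface == text[start:end]`.

## Entity detection

31 entity types are recognized. Detection is rule-based: one detector per
type behind a registry (`rtindex.detect.DetectorRegistry`), so a trained
sequence model can replace any lexicon detector without touching callers.
Cue lexicons are shipped as data files (one per type; `#` comments; `re:`
prefix marks a regex line; plain lines are literal phrases matched
case-insensitively on word boundaries). The bundled lexicons and
identifier/accession patterns (GEO/SRA/BioProject accessions, repository
DOIs, protocol and code-hosting URLs, RRID shapes per registry prefix) are
reconstructions authored for this package, not a published pattern set;
coverage is therefore configurable data, not code.

Conventions:

* Overlapping mentions of the same type merge to the widest covering span;
  different types overlap freely.
* Euthanasia statements and euthanasia agents are one `euthanasia` type.
* RRID tokens require the `RRID:` prefix plus a registry-shaped accession
  with minimum length (so truncated tokens like `AB_0` are rejected).
  Identifier validity is checked offline against these shape rules only; no
  resolver is queried, so existence of an accession is never asserted.
* Sentence boundaries (needed for RRID–resource co-occurrence) come from a
  rule splitter: sentence-final punctuation + whitespace + uppercase, with
  a whole-token abbreviation guard list.
* A resource mention is *identifiable* when an RRID occurs in the same
  sentence or its normalized surface has an entry in the bundled
  name-to-RRID suggestion catalog (`data/resource_catalog.json`).
* A detector that raises is logged and reported as failed for that type,
  never silently empty.

## Conditional scoring

The scoring table (15 groupings, memberships, trigger relations, which
component each grouping feeds) lives in `data/scoring_rules.json`; the
engine is data-driven and contains no grouping-specific code. Expectation
logic: randomization, blinding and power analysis are always expected;
detecting a grouping adds its triggered groupings; never-expected groupings
(field permits, euthanasia, replication, cell lines) are excluded from the
expected set even when detected.

Decisions taken where the scoring description is underdetermined:

* **Grouping-level counting.** Found and expected are counted at grouping
  level, not criterion level: a detected scoring grouping counts as found
  whether or not it is itself in the expected set, and the expected count is
  the size of the triggered union. This is the only reading consistent with
  the canonical worked example (ethics approval + age ⇒ found 2 of
  expected 6), and it is pinned by an exhaustive test of all 2^15 grouping
  subsets against a straight-line oracle.
* **Never-expected still rewarded.** Detected never-expected groupings
  count toward found; reporting them is rewarded, never demanded. The
  found/expected ratio is capped at 1, so rigor points stay in [0, 5].
* **Single-component papers.** Nothing specifies how a 5-point component
  becomes a 10-point total when the other component is inapplicable (no
  resources detected, or no rigor grouping detected). Default: the
  applicable component is rescaled to 10, so resource-free study designs
  are not structurally penalized; a `sum` mode adds raw points instead.
* **Rounding.** Scores are kept as reals; the integer display scale rounds
  half-up (5·2/6 ≈ 1.67 displays as 2).
* **Not applicable.** A paper whose only detections are non-scoring types
  (availability statements, identifiers, statistical tests,
  oligonucleotides), or with no detections at all, scores 0 and is excluded
  from every downstream mean.

Monotonicity holds by construction and is property-tested: adding a
detected grouping that was expected but missing never lowers rigor points.

## Affiliation disambiguation

Raw affiliation strings are split on all semicolons; each segment is
processed independently, so a paper credits several institutions, or one
institution several times. The institution-name candidate is the first
comma-delimited chunk containing an institution keyword
(university/institute/college/hospital/center/centre/academy/school/
clinic/foundation/laboratory — a reconstruction shipped as config), with
leading non-uppercase junk stripped (`^[^A-Z]*`). Matching against the
registry (ROR-style ids, names, aliases, countries):

* exact normalized hit on one record → high confidence;
* exact hit shared by several records, or the unique best fuzzy hit at or
  above threshold → low confidence, ties broken by smallest id;
* otherwise no match.

Normalization casefolds, strips diacritics, drops punctuation and collapses
whitespace. Fuzzy similarity is the Dice coefficient over normalized unique
token sets; the default threshold 0.9 is configurable (the high/low tier
split implies a threshold but none is published). Department names are
extracted with the published keyword pattern, applied case-insensitively,
first match, junk-stripped. Country attribution always comes from the
matched registry record, never from parsing the raw string. Matching
accuracy is evaluated as exact agreement with a curated key (agreed
no-match counts as agreement), reported for high-only and high+low tiers.

## Aggregation

The index of a group is the arithmetic mean of per-paper totals over scored
(total > 0) papers, per group-year, emitted only when strictly more than
`threshold` (default 10) papers were scored. Multi-affiliation papers
contribute once per matched institution, with multiplicity; a dedupe switch
exists and defaults off. Rank reports first keep the `volume_cut` (default
50) most prolific groups of a year, then order by index descending (ties:
larger paper count, then key) and emit the top `top_k` (default 25).
Criteria trends report the per-year proportion of cohort papers addressing
a criterion; compound criteria (replication, data, code) are addressed when
any member type is detected, and the cell-line cohort keeps papers with at
least one cell line and neither IRB nor IACUC detections. The corpus-wide
index is a per-paper mean (papers, not journals, are the units).

## Department clustering

Word vectors are trained on a seeded random sample (default 1%) of the
abstract corpus, after removing comment/erratum/review/preprint articles.
The trainer is count-based: symmetric-window (5) co-occurrence counts,
positive-PMI reweighting, truncated SVD to the target dimension (default
300; when the sampled vocabulary is smaller than the dimension the spectrum
is exhausted and the remaining components are zero-padded). Rows are
L2-normalized. Out-of-vocabulary tokens fall back to character-3–5-gram
vectors (mean of training words sharing the n-gram); an abstract with no
embeddable token is flagged and excluded. An abstract vector is the
L2-normalized mean of its token vectors, so token order is irrelevant.

Department identity is (extracted department name, matched top-level
institution); profiles require more than 200 papers and average the
abstract vectors. Profiles are reduced to 2-D with t-SNE (perplexity 7,
PCA initialization, seeded) and clustered with k-means (k = 10, seeded,
`n_init` 10) **on the 2-D coordinates** — a statistically debatable but
deliberate choice matching the procedure this pipeline reproduces; a flag
clusters the full-dimensional vectors instead. Rankings by index value are
produced within clusters only; t-SNE layouts are seed-dependent and no
particular published layout is reproducible.

## Evaluation statistics

Precision tp/(tp+fp), recall tp/(tp+fn), F1 = 2PR/(P+R) with F1 = 0 at
P = R = 0; vanished denominators raise (undefined, never silently 0).
Curator-vs-classifier agreement is presence/absence per paper per type
(span-level credit is not attempted); disagreements split into false
positives/negatives with the curator always correct. Spearman correlation
is the Pearson correlation of rank vectors with average ranks for ties
(cross-checked against `scipy.stats.spearmanr` in the tests), undefined for
constant input. The first-order partial correlation is
(r_ab − r_ac·r_bc)/√((1−r_ac²)(1−r_bc²)), undefined when the adjusting
variable correlates perfectly with either other variable. Applied to the
published staff/revenue/index coefficient triple (−0.1209, −0.1648, 0.6208)
it yields −0.1153, which matches the published −0.1154 within the rounding
of the printed 4-decimal inputs.

## Synthetic corpora

`rtindex.synth` renders planted entities with sentences drawn from the
detectors' own cue lexicons, one sentence per type, interleaved with inert
filler; a per-type exclusivity test guarantees each plant fires exactly its
own detector. Planted resources optionally carry inline RRIDs
(`rrid_rate`, default 0.30) or are catalog-identifiable. Default plant
rates use reported literature-wide addressment proportions where such
figures exist (randomization 0.31, blinding 0.09, power 0.08, data
availability 0.15, code availability 0.03) and magnitudes typical of
biomedical methods sections elsewhere; they are the package's standing
study conditions, not tuning knobs. Affiliations are built from a synthetic
registry (`Department of X, <name>, <country>`) with character-level
substitution noise at a configurable rate; abstracts are drawn from
configurable topic vocabularies. Everything derives from one seeded
generator, so corpora are byte-identical across runs.

Ground-truth expected scores are computed by a straight-line, hard-coded
transcription of the scoring table that shares no code with the engine —
an independent oracle, so the two can disagree meaningfully. A paraphrase
tier renders some plants with wordings the lexicons do not cover; recall on
that tier is measured, never asserted.

What passing on synthetic corpora shows: the pipeline's plumbing and
scoring logic are exact. What it does not show: real-world detector recall
— real prose paraphrases freely, reports entities in tables and
supplementary files, and correlates reporting behaviors; the generator
plants types independently and uses the detectors' own vocabulary. The
paraphrase tier exists precisely to keep this gap visible.

## Problem sizes and defaults

End-to-end validation uses a 500-paper corpus (seeded), 4 journals, 5
years, 50 institutions — large enough that every journal-year cell clears
the >10 inclusion rule while the full suite stays fast. Clustering tests
use three disjoint topic vocabularies of ~15 words, 30 documents per topic,
embedding dimension 20; t-SNE perplexity is clamped to (n−1)/3 for tiny
inputs. Default thresholds everywhere carry the standing values: >10
scored papers per group-year, volume cut 50, top 25, department minimum
200 papers, fuzzy threshold 0.9, embedding sample fraction 0.01 and
dimension 300, perplexity 7, k = 10.

## Known limitations

* Rule-based detectors trade recall for transparency; the detector
  interface accepts trained models but none ship with the package.
* Antibody double counting across a reagent table and the prose that
  repeats it is documented behavior, not solved.
* Criteria reported outside the methods section (attrition in results,
  availability statements in dedicated end-sections) are missed, by the
  section-restriction design.
* Identifier existence is never verified against live resolvers.
* One institution match per segment: a segment naming two institutions in
  one comma chunk yields only the first.
* The exact historical behavior for rigor-only papers' totals is not
  independently verifiable; the rescale default is this package's choice
  and the `sum` mode preserves the alternative.
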