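"""Disambiguate raw affiliation strings against an institution registry.

Builds a small synthetic registry, then walks the matching workflow on a few
affiliation strings: semicolon splitting, institution-name extraction by
keyword chunk, and registry lookup with exact (high-confidence) and fuzzy
(low-confidence) tiers. Finally evaluates matcher output against a
hand-curated answer key the way a curation study would.
"""

from rtindex import affil, synth

records = synth.generate_registry(20, seed=7)
registry = affil.Registry(
    [affil.RegistryRecord(r["id"], r["name"], tuple(r["aliases"]), r["country"])
     for r in records]
)
inst = records[0]
print(f"registry of {len(registry)} institutions; first: {inst['name']} ({inst['id']})")

raw = (f"Department of Neuroscience, {inst['name']}, {inst['country']}; "
       f"Department of Physiology, {inst['name']}, {inst['country']}")
print(f"\naffiliation string:\n  {raw}")
for m in affil.match_affiliation(raw, registry):
    dept = affil.extract_department(m.segment)
    print(f"  segment -> id={m.id} confidence={m.confidence} country={m.country} dept={dept!r}")
# Two segments resolve to the same institution: the paper counts twice for it.

shortened = inst["name"].replace(" of ", " ")  # "University of X" -> "University X"
m = affil.match_institution(shortened, registry, threshold=0.7)
print(f"\nfuzzy: {shortened!r} -> id={m.id} confidence={m.confidence} score={m.score:.2f}")

tool = {"a1": (inst["id"], "high"), "a2": (None, "none"), "a3": ("WRONG", "low")}
curated = {"a1": inst["id"], "a2": None, "a3": records[1]["id"]}
print("\naccuracy vs curated key:", affil.evaluate_matching(tool, curated))
# high tier counts only high-confidence predictions; agreement includes
# agreed no-matches.
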