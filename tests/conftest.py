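import pytest

from rtindex import affil, synth


def make_jats(
    methods: str | None = "Cells were cultured as described.",
    abstract: str | None = "A short abstract.",
    journal: str = "Journal of Testing",
    year: int = 2020,
    affiliations: tuple[str, ...] = (),
    publication_types: tuple[str, ...] = (),
    sec_type: str | None = "methods",
    sec_title: str = "Materials and Methods",
    pmcid: str = "PMC000001",
) -> str:
    """Hand-rolled minimal JATS document for parser tests."""
    affs = "".join(f"<aff>{a}</aff>" for a in affiliations)
    cats = ""
    if publication_types:
        subjects = "".join(f"<subject>{t}</subject>" for t in publication_types)
        cats = f"<article-categories><subj-group>{subjects}</subj-group></article-categories>"
    abstract_xml = f"<abstract><p>{abstract}</p></abstract>" if abstract else ""
    body = ""
    if methods is not None:
        attr = f' sec-type="{sec_type}"' if sec_type else ""
        body = f'<sec{attr}><title>{sec_title}</title><p>{methods}</p></sec>'
    return f"""<?xml version="1.0"?>
<article article-type="research-article">
  <front>
    <journal-meta><journal-title-group><journal-title>{journal}</journal-title></journal-title-group></journal-meta>
    <article-meta>
      <article-id pub-id-type="pmcid">{pmcid}</article-id>
      {cats}
      <pub-date><year>{year}</year></pub-date>
      {affs}
      {abstract_xml}
    </article-meta>
  </front>
  <body>{body}</body>
</article>"""


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-paper synthetic corpus with default plant rates."""
    spec = synth.CorpusSpec(seed=11, n_papers=60, n_institutions=20, n_journals=2)
    articles, truth, registry = synth.generate_corpus(spec)
    return articles, truth, registry


@pytest.fixture(scope="session")
def institution_registry(small_corpus):
    _, _, registry = small_corpus
    return affil.Registry(
        [
            affil.RegistryRecord(r["id"], r["name"], tuple(r["aliases"]), r["country"])
            for r in registry
        ]
    )
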