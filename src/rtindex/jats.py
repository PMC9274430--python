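"""Reading and writing JATS XML articles.

This module exposes the text units the scoring pipeline consumes: article
metadata, the abstract, raw affiliation strings, the materials-and-methods
section (including any tables nested inside it), and publication types.
Articles only available as PDFs or supplementary files are invisible to the
pipeline by design; only the JATS body is read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from lxml import etree

__all__ = [
    "JATSError",
    "JATSParseError",
    "UnsupportedFormatError",
    "Manuscript",
    "TableBlock",
    "parse_article",
    "select_methods_section",
    "filter_abstract_corpus",
    "manuscript_to_jats",
    "manuscript_to_record",
    "write_jsonl",
    "read_corpus",
    "METHODS_SEC_TYPES",
    "METHODS_TITLES",
    "EXCLUDED_PUBLICATION_TYPES",
]


class JATSError(Exception):
    """Base class for article I/O failures."""


class JATSParseError(JATSError):
    """Malformed XML; message carries the parser's line/column position."""


class UnsupportedFormatError(JATSError):
    """Well-formed XML whose root element is not a JATS <article>."""


# sec-type values and (case-insensitive) section titles accepted as the
# materials-and-methods section. JATS itself does not constrain sec-type
# values, so this lexicon is deliberately editable.
METHODS_SEC_TYPES = frozenset(
    {"methods", "materials|methods", "materials-and-methods"}
)
METHODS_TITLES = frozenset(
    {
        "methods",
        "materials and methods",
        "methods and materials",
        "experimental procedures",
        "star methods",
    }
)

# Publication types removed when building the abstract corpus used for
# semantic department grouping.
EXCLUDED_PUBLICATION_TYPES = frozenset(
    {"comment", "published erratum", "review", "preprint"}
)


@dataclass
class TableBlock:
    """One table: a caption plus rows of plain-text cells (tags stripped)."""

    caption: str = ""
    rows: list[list[str]] = field(default_factory=list)


@dataclass
class Manuscript:
    """A parsed article.

    ``methods_text`` and ``abstract`` are ``None`` (never the empty string)
    when the corresponding unit is absent from the document. A manuscript
    without a methods section is excluded from scoring.
    """

    id: str
    journal: str | None = None
    year: int | None = None
    country_strings: list[str] = field(default_factory=list)
    abstract: str | None = None
    methods_text: str | None = None
    tables: list[TableBlock] = field(default_factory=list)
    publication_types: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        """True when the article has no methods section and cannot be scored."""
        return self.methods_text is None


def _text_of(node: etree._Element | None) -> str:
    if node is None:
        return ""
    return " ".join("".join(node.itertext()).split())


def _parse_tree(source: Union[str, bytes, Path, etree._Element]) -> etree._Element:
    if isinstance(source, etree._Element):
        return source
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, Path):
            root = etree.parse(str(source)).getroot()
        elif isinstance(source, str) and not source.lstrip().startswith("<"):
            root = etree.parse(source).getroot()
        else:
            root = etree.fromstring(source.encode())
    except etree.XMLSyntaxError as exc:
        raise JATSParseError(f"malformed XML: {exc}") from exc
    if root.tag != "article":
        raise UnsupportedFormatError(
            f"root element is <{root.tag}>, expected JATS <article>"
        )
    return root


def _parse_table(table_wrap: etree._Element) -> TableBlock:
    caption = _text_of(table_wrap.find("caption"))
    rows: list[list[str]] = []
    for tr in table_wrap.iter("tr"):
        cells = [_text_of(td) for td in tr if td.tag in ("td", "th")]
        if cells:
            rows.append(cells)
    return TableBlock(caption=caption, rows=rows)


def _is_methods_sec(sec: etree._Element) -> bool:
    sec_type = (sec.get("sec-type") or "").strip().lower()
    if sec_type in METHODS_SEC_TYPES:
        return True
    title = _text_of(sec.find("title")).lower()
    return title in METHODS_TITLES


def _methods_secs(root: etree._Element) -> list[etree._Element]:
    body = root.find("body")
    if body is None:
        return []
    return [sec for sec in body.iter("sec") if _is_methods_sec(sec)]


def select_methods_section(source: Union[Manuscript, etree._Element]) -> str | None:
    """Return the concatenated methods text, or ``None`` when absent.

    Paragraphs of the methods section and all of its nested subsections are
    concatenated in document order; the cell text of any table nested inside
    the methods subtree is appended after the prose. Text outside the methods
    subtree never leaks in.
    """
    if isinstance(source, Manuscript):
        return source.methods_text
    secs = _methods_secs(source)
    if not secs:
        return None
    paragraphs: list[str] = []
    table_texts: list[str] = []
    for sec in secs:
        for node in sec.iter():
            if node.tag == "p" and node.getparent().tag != "table-wrap":
                paragraphs.append(_text_of(node))
        for tw in sec.iter("table-wrap"):
            block = _parse_table(tw)
            parts = [block.caption] if block.caption else []
            parts.extend(" ".join(row) for row in block.rows)
            table_texts.append(" ".join(p for p in parts if p))
    text = " ".join(p for p in paragraphs + table_texts if p)
    return text if text else None


def parse_article(source: Union[str, bytes, Path], article_id: str | None = None) -> Manuscript:
    """Parse one JATS article (path, string, or bytes) into a :class:`Manuscript`."""
    root = _parse_tree(source)
    meta = root.find("front/article-meta")

    doc_id = article_id
    if meta is not None:
        for id_type in ("pmcid", "pmc", "pmid", "doi", "publisher-id"):
            node = meta.find(f"article-id[@pub-id-type='{id_type}']")
            if node is not None and _text_of(node):
                doc_id = _text_of(node)
                break
    if doc_id is None and isinstance(source, (str, Path)) and "\n" not in str(source):
        doc_id = Path(str(source)).stem
    if doc_id is None:
        doc_id = "unknown"

    journal = None
    jnode = root.find("front/journal-meta//journal-title")
    if jnode is not None and _text_of(jnode):
        journal = _text_of(jnode)

    year = None
    if meta is not None:
        ynode = meta.find("pub-date/year")
        if ynode is not None:
            ytext = _text_of(ynode)
            if ytext.isdigit() and len(ytext) == 4:
                year = int(ytext)

    affiliations: list[str] = []
    if meta is not None:
        for aff in meta.iter("aff"):
            # drop numeric <label> markers; keep the address text itself
            chunks: list[str] = [aff.text or ""]
            for child in aff:
                if child.tag != "label":
                    chunks.append("".join(child.itertext()))
                chunks.append(child.tail or "")
            text = " ".join(" ".join(chunks).split())
            if text:
                affiliations.append(text)

    abstract = None
    if meta is not None:
        anode = meta.find("abstract")
        if anode is not None:
            atext = _text_of(anode)
            abstract = atext if atext else None

    publication_types: list[str] = []
    atype = root.get("article-type")
    if atype:
        publication_types.append(atype)
    if meta is not None:
        for subj in meta.findall("article-categories//subject"):
            stext = _text_of(subj)
            if stext and stext not in publication_types:
                publication_types.append(stext)

    methods_text = select_methods_section(root)

    tables = []
    for sec in _methods_secs(root):
        tables.extend(_parse_table(tw) for tw in sec.iter("table-wrap"))

    return Manuscript(
        id=doc_id,
        journal=journal,
        year=year,
        country_strings=affiliations,
        abstract=abstract,
        methods_text=methods_text,
        tables=tables,
        publication_types=publication_types,
    )


def filter_abstract_corpus(manuscripts: Iterable[Manuscript]) -> list[Manuscript]:
    """Keep manuscripts with an abstract and none of the excluded publication types."""
    kept = []
    for m in manuscripts:
        if m.abstract is None:
            continue
        types = {t.strip().lower() for t in m.publication_types}
        if types & EXCLUDED_PUBLICATION_TYPES:
            continue
        kept.append(m)
    return kept


def manuscript_to_jats(m: Manuscript) -> bytes:
    """Serialize a :class:`Manuscript` back to a minimal JATS document.

    Round-trips through :func:`parse_article`: every populated field survives.
    Used by the synthetic-corpus generator.
    """
    root = etree.Element("article")
    if m.publication_types:
        root.set("article-type", m.publication_types[0])
    front = etree.SubElement(root, "front")
    jm = etree.SubElement(front, "journal-meta")
    if m.journal is not None:
        tg = etree.SubElement(jm, "journal-title-group")
        etree.SubElement(tg, "journal-title").text = m.journal
    am = etree.SubElement(front, "article-meta")
    idn = etree.SubElement(am, "article-id", attrib={"pub-id-type": "pmcid"})
    idn.text = m.id
    if len(m.publication_types) > 1:
        cats = etree.SubElement(am, "article-categories")
        sg = etree.SubElement(cats, "subj-group")
        for t in m.publication_types[1:]:
            etree.SubElement(sg, "subject").text = t
    if m.year is not None:
        pd = etree.SubElement(am, "pub-date")
        etree.SubElement(pd, "year").text = str(m.year)
    for aff_text in m.country_strings:
        etree.SubElement(am, "aff").text = aff_text
    if m.abstract is not None:
        ab = etree.SubElement(am, "abstract")
        etree.SubElement(ab, "p").text = m.abstract
    body = etree.SubElement(root, "body")
    if m.methods_text is not None:
        sec = etree.SubElement(body, "sec", attrib={"sec-type": "methods"})
        etree.SubElement(sec, "title").text = "Materials and Methods"
        etree.SubElement(sec, "p").text = m.methods_text
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def manuscript_to_record(m: Manuscript) -> dict:
    """Manuscript as a plain JSON-serializable record (one line of JSONL)."""
    return {
        "id": m.id,
        "journal": m.journal,
        "year": m.year,
        "country_strings": list(m.country_strings),
        "abstract": m.abstract,
        "methods_text": m.methods_text,
        "tables": [{"caption": t.caption, "rows": t.rows} for t in m.tables],
        "publication_types": list(m.publication_types),
        "excluded": m.excluded,
    }


def write_jsonl(manuscripts: Sequence[Manuscript], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in manuscripts:
            fh.write(json.dumps(manuscript_to_record(m)) + "\n")


def read_corpus(directory: Union[str, Path]) -> list[Manuscript]:
    """Parse every ``*.xml`` file under a directory tree, sorted by path."""
    paths = sorted(Path(directory).rglob("*.xml"))
    return [parse_article(p) for p in paths]
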