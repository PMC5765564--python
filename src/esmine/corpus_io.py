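"""Readers and writers for citation corpora and the tabular ES database.

Handles the MEDLINE/PubMed citation XML dialect (``PubmedArticleSet``) and
JATS full-text XML, turning them into neutral in-memory records, plus a
TSV round-trip for detected-mention tables.  Gzip input is detected by magic
bytes, so callers can pass either plain or compressed streams/paths.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Union

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}

# NBSP and thin/narrow spaces become plain spaces at read time; dashes and the
# Unicode minus are left untouched here — normalising them is the detector's
# job, and it must see the text at its original offsets.
_SPACE_MAP = {0x00A0: " ", 0x2009: " ", 0x200A: " ", 0x202F: " "}

_SKIP_LABELS = {"copyright", "funding", "funding statement"}


@dataclass
class CitationRecord:
    """One PubMed citation reduced to the fields the pipeline consumes."""

    pmid: str
    pmcid: str | None = None
    abstract_text: str = ""
    pub_year: int = 0
    pub_month: int | None = None
    journal_title: str = ""
    journal_issn: str | None = None
    pub_types: set[str] = field(default_factory=set)
    mesh_descriptors: set[str] = field(default_factory=set)
    affiliations: list[str] = field(default_factory=list)


@dataclass
class FullTextRecord:
    """A JATS article split into the three extraction channels.

    The channels (abstract, Results-section paragraphs, table cells) are
    disjoint scopes: text mined from one never reappears in another.
    """

    pmcid: str
    abstract_text: str = ""
    results_paragraphs: list[str] = field(default_factory=list)
    table_cells: list[str] = field(default_factory=list)


Source = Union[str, Path, IO[bytes], bytes]


def _open_stream(source: Source) -> IO[bytes]:
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    if isinstance(source, (str, Path)):
        source = open(source, "rb")
    head = source.read(2)
    source.seek(0)
    if head == b"\x1f\x8b":
        return gzip.open(source, "rb")  # type: ignore[return-value]
    return source


def _clean_text(s: str) -> str:
    s = s.translate(_SPACE_MAP)
    return re.sub(r"\s+", " ", s).strip()


def _parse_pub_date(article: etree._Element) -> tuple[int, int | None]:
    """Resolve (year, month) from a PubDate element.

    Structured Year/Month children are preferred.  A free-form MedlineDate
    such as ``1994 Dec-1995 Jan`` resolves to its first 4-digit year and the
    first recognizable month token (1994, 12).  A missing month stays absent —
    downstream monthly series simply exclude the citation rather than
    fabricating a month.
    """
    pd_el = article.find(".//JournalIssue/PubDate")
    if pd_el is None:
        return 0, None
    year_el = pd_el.findtext("Year")
    month_el = pd_el.findtext("Month")
    if year_el:
        year = int(year_el)
        month = None
        if month_el:
            m = month_el.strip()
            if m.isdigit():
                month = int(m)
            else:
                month = _MONTHS.get(m[:3].lower())
        return year, month
    medline = pd_el.findtext("MedlineDate") or ""
    ym = re.search(r"\b(1[89]\d\d|20\d\d)\b", medline)
    year = int(ym.group(1)) if ym else 0
    month = None
    for token in re.split(r"[\s\-/]+", medline):
        mo = _MONTHS.get(token[:3].lower())
        if mo:
            month = mo
            break
    return year, month


def _assemble_abstract(article: etree._Element) -> str:
    parts = []
    for at in article.findall(".//Abstract/AbstractText"):
        label = (at.get("Label") or "").strip().lower()
        category = (at.get("NlmCategory") or "").strip().lower()
        if label in _SKIP_LABELS or category in _SKIP_LABELS:
            continue
        text = "".join(at.itertext())
        if text:
            parts.append(text)
    return _clean_text(" ".join(parts))


def parse_pubmed_citations(source: Source) -> Iterator[CitationRecord]:
    """Stream `CitationRecord`s out of a ``PubmedArticleSet`` XML document.

    Parsing is incremental (constant memory in corpus size).  Citations
    without an abstract are still emitted, with ``abstract_text == ""``, so
    callers can account for exclusions; citations without a PMID are skipped
    with a warning.  Malformed XML raises ``lxml.etree.XMLSyntaxError``.
    """
    stream = _open_stream(source)
    for _event, el in etree.iterparse(stream, events=("end",), tag="PubmedArticle"):
        pmid = el.findtext(".//MedlineCitation/PMID")
        if not pmid:
            logger.warning("citation without PMID skipped")
        else:
            pmcid = None
            for aid in el.findall(".//PubmedData/ArticleIdList/ArticleId"):
                if aid.get("IdType") == "pmc":
                    pmcid = (aid.text or "").strip() or None
            year, month = _parse_pub_date(el)
            pub_types = {
                _clean_text(pt.text or "")
                for pt in el.findall(".//PublicationTypeList/PublicationType")
                if pt.text
            }
            mesh = {
                _clean_text(d.text or "")
                for d in el.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
                if d.text
            }
            affiliations = [
                _clean_text(a.text or "")
                for a in el.findall(".//AuthorList/Author/AffiliationInfo/Affiliation")
                if a.text
            ]
            yield CitationRecord(
                pmid=pmid.strip(),
                pmcid=pmcid,
                abstract_text=_assemble_abstract(el),
                pub_year=year,
                pub_month=month,
                journal_title=_clean_text(el.findtext(".//Journal/Title") or ""),
                journal_issn=(el.findtext(".//Journal/ISSN") or None),
                pub_types=pub_types,
                mesh_descriptors=mesh,
                affiliations=affiliations,
            )
        el.clear()
        parent = el.getparent()
        if parent is not None:
            while el.getprevious() is not None:
                del parent[0]


_RESULTS_TITLE = re.compile(r"result", re.I)


def parse_pmc_fulltext(source: Source, results_pattern: re.Pattern | str = _RESULTS_TITLE) -> FullTextRecord:
    """Parse one JATS article into abstract / Results paragraphs / table cells.

    A section feeds ``results_paragraphs`` when its ``<title>`` matches
    ``results_pattern`` (default: case-insensitive ``result``, so "Results and
    Discussion" qualifies).  Table cells are flattened in row-major order.
    An article without a Results-matching section is not an error.
    """
    if isinstance(results_pattern, str):
        results_pattern = re.compile(results_pattern, re.I)
    tree = etree.parse(_open_stream(source))
    root = tree.getroot()

    pmcid = ""
    for el in root.findall(".//front//article-id"):
        if el.get("pub-id-type") in ("pmc", "pmcid"):
            pmcid = _clean_text("".join(el.itertext()))

    abstract_parts = [
        _clean_text("".join(p.itertext())) for p in root.findall(".//front//abstract//p")
    ]
    abstract = _clean_text(" ".join(abstract_parts))

    results_paragraphs: list[str] = []
    for sec in root.findall(".//body//sec"):
        title = "".join(sec.findtext("title") or "")
        if not results_pattern.search(title):
            continue
        for p in sec.findall(".//p"):
            txt = _clean_text("".join(p.itertext()))
            if txt:
                results_paragraphs.append(txt)

    table_cells: list[str] = []
    for tw in root.findall(".//table-wrap"):
        for cell in tw.iter("td", "th"):
            txt = _clean_text("".join(cell.itertext()))
            table_cells.append(txt)

    return FullTextRecord(
        pmcid=pmcid,
        abstract_text=abstract,
        results_paragraphs=results_paragraphs,
        table_cells=table_cells,
    )


# ---------------------------------------------------------------------------
# Tabular ES database (TSV interchange)

ES_TABLE_COLUMNS = [
    "source_id", "es_type", "adjusted", "value",
    "ci_level", "ci_lower", "ci_upper",
    "span_start", "span_end", "flags",
]

_REQUIRED_COLUMNS = {"source_id", "es_type", "value"}


def write_es_table(rows, path: Union[str, Path]) -> int:
    """Write mention rows to ``path`` as header + TSV; returns the row count.

    ``rows`` may be a DataFrame or an iterable of dicts sharing one schema.
    Absent values are encoded as empty strings so that the paired reader
    round-trips field-for-field.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows), columns=ES_TABLE_COLUMNS)
    rows.to_csv(path, sep="\t", index=False, na_rep="")
    return len(rows)


def read_es_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a mention TSV written by :func:`write_es_table`.

    Raises ``ValueError`` naming the offending column when a required column
    is missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str})
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"ES table at {path} is missing column(s): {sorted(missing)}")
    return df
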