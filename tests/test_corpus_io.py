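"""Citation/full-text parsing and the ES-table TSV round trip."""

import gzip
import io

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from esmine.corpus_io import (
    ES_TABLE_COLUMNS,
    parse_pmc_fulltext,
    parse_pubmed_citations,
    read_es_table,
    write_es_table,
)


def _citation(pmid, abstract="", year="1994", month="Dec", medline_date=None,
              review=False, structured=False):
    if medline_date:
        date = f"<MedlineDate>{medline_date}</MedlineDate>"
    else:
        date = f"<Year>{year}</Year><Month>{month}</Month>"
    if structured:
        abstract_xml = (
            "<Abstract>"
            '<AbstractText Label="BACKGROUND">Background text.</AbstractText>'
            f'<AbstractText Label="RESULTS">{abstract}</AbstractText>'
            '<AbstractText Label="COPYRIGHT">(c) Synthetic Press.</AbstractText>'
            "</Abstract>"
        )
    elif abstract:
        abstract_xml = f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>"
    else:
        abstract_xml = ""
    pub_types = "<PublicationType>Journal Article</PublicationType>"
    if review:
        pub_types += "<PublicationType>Review</PublicationType>"
    return f"""
    <PubmedArticle><MedlineCitation><PMID>{pmid}</PMID>
      <Article>
        <Journal><ISSN>0028-4793</ISSN>
          <JournalIssue><PubDate>{date}</PubDate></JournalIssue>
          <Title>The New England Journal of Medicine</Title></Journal>
        <ArticleTitle>T</ArticleTitle>
        {abstract_xml}
        <AuthorList><Author><LastName>A</LastName>
          <AffiliationInfo><Affiliation>Toulouse University Hospital, Toulouse, France.</Affiliation></AffiliationInfo>
        </Author></AuthorList>
        <PublicationTypeList>{pub_types}</PublicationTypeList>
      </Article>
      <MeshHeadingList><MeshHeading><DescriptorName>Neoplasms</DescriptorName></MeshHeading></MeshHeadingList>
    </MedlineCitation></PubmedArticle>"""


def _corpus(*citations):
    return ("<?xml version='1.0'?><PubmedArticleSet>"
            + "".join(citations) + "</PubmedArticleSet>").encode()


class TestParsePubmed:
    def test_counts_and_abstract_presence(self):
        xml = _corpus(
            _citation("1", abstract="OR = 2.0 (95% CI 1.5-2.7)."),
            _citation("2", abstract="Plain text."),
            _citation("3"),
        )
        records = list(parse_pubmed_citations(xml))
        assert len(records) == 3
        assert sum(1 for r in records if r.abstract_text) == 2

    def test_empty_set_yields_nothing(self):
        assert list(parse_pubmed_citations(_corpus())) == []

    def test_medline_date_first_token_rule(self):
        xml = _corpus(_citation("1", abstract="x", medline_date="1994 Dec-1995 Jan"))
        (rec,) = parse_pubmed_citations(xml)
        assert (rec.pub_year, rec.pub_month) == (1994, 12)

    def test_medline_date_without_month(self):
        xml = _corpus(_citation("1", abstract="x", medline_date="1994 Winter"))
        (rec,) = parse_pubmed_citations(xml)
        assert rec.pub_year == 1994
        assert rec.pub_month is None

    def test_structured_abstract_drops_labels_and_copyright(self):
        xml = _corpus(_citation("1", abstract="Main result here.", structured=True))
        (rec,) = parse_pubmed_citations(xml)
        assert rec.abstract_text == "Background text. Main result here."
        assert "BACKGROUND" not in rec.abstract_text
        assert "Synthetic Press" not in rec.abstract_text

    def test_metadata_fields(self):
        xml = _corpus(_citation("7", abstract="x", review=True))
        (rec,) = parse_pubmed_citations(xml)
        assert rec.journal_issn == "0028-4793"
        assert "Review" in rec.pub_types
        assert rec.mesh_descriptors == {"Neoplasms"}
        assert any("France" in a for a in rec.affiliations)

    def test_gzip_transparency(self):
        xml = _corpus(_citation("1", abstract="x"))
        records = list(parse_pubmed_citations(gzip.compress(xml)))
        assert len(records) == 1

    def test_missing_pmid_skipped(self):
        bad = "<PubmedArticle><MedlineCitation></MedlineCitation></PubmedArticle>"
        xml = ("<PubmedArticleSet>" + bad + _citation("1", abstract="x")
               + "</PubmedArticleSet>").encode()
        records = list(parse_pubmed_citations(xml))
        assert [r.pmid for r in records] == ["1"]


JATS = b"""<?xml version='1.0'?>
<article>
  <front>
    <article-meta><article-id pub-id-type="pmc">PMC42</article-id>
      <abstract><p>Abstract text.</p></abstract></article-meta>
  </front>
  <body>
    <sec><title>Introduction</title><p>Intro paragraph.</p></sec>
    <sec><title>Results and Discussion</title><p>First result.</p><p>Second result.</p></sec>
    <table-wrap><table><tr><td>a</td><td>b</td><td>c</td></tr>
      <tr><td>d</td><td>e</td><td>f</td></tr></table></table-wrap>
  </body>
</article>"""


class TestParseJats:
    def test_results_section_matching(self):
        rec = parse_pmc_fulltext(JATS)
        assert rec.pmcid == "PMC42"
        assert rec.abstract_text == "Abstract text."
        assert rec.results_paragraphs == ["First result.", "Second result."]

    def test_table_cells_flattened(self):
        rec = parse_pmc_fulltext(JATS)
        assert rec.table_cells == list("abcdef")

    def test_no_results_section_not_an_error(self):
        xml = JATS.replace(b"Results and Discussion", b"Methods")
        rec = parse_pmc_fulltext(xml)
        assert rec.results_paragraphs == []


row_strategy = st.fixed_dictionaries({
    "source_id": st.text(alphabet="0123456789", min_size=1, max_size=8),
    "es_type": st.sampled_from(["OR", "RR", "HR"]),
    "adjusted": st.booleans(),
    "value": st.floats(0.01, 1000, allow_nan=False).map(lambda x: round(x, 4)),
    "ci_level": st.sampled_from([90, 95, 99, None]),
    "ci_lower": st.one_of(st.none(), st.floats(0.01, 10).map(lambda x: round(x, 4))),
    "ci_upper": st.one_of(st.none(), st.floats(10, 100).map(lambda x: round(x, 4))),
    "span_start": st.integers(0, 500),
    "span_end": st.integers(0, 500),
    "flags": st.sampled_from(["", "no_ci", "no_ci,restrictive_mode"]),
})


class TestEsTable:
    def test_header_plus_rows(self, tmp_path):
        rows = [dict.fromkeys(ES_TABLE_COLUMNS, "") | {"source_id": "1", "es_type": "OR", "value": 2.0}
                for _ in range(2)]
        n = write_es_table(rows, tmp_path / "t.tsv")
        assert n == 2
        assert len((tmp_path / "t.tsv").read_text().splitlines()) == 3

    def test_missing_value_column_raises(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("source_id\tes_type\n1\tOR\n")
        with pytest.raises(ValueError, match="value"):
            read_es_table(tmp_path / "bad.tsv")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rows=st.lists(row_strategy, min_size=1, max_size=8))
    def test_round_trip_identity(self, rows, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        df = pd.DataFrame(rows, columns=ES_TABLE_COLUMNS)
        write_es_table(df, tmp / "t.tsv")
        back = read_es_table(tmp / "t.tsv")
        for col in ES_TABLE_COLUMNS:
            for orig, rt in zip(df[col], back[col]):
                if orig is None or orig == "" or (isinstance(orig, float) and pd.isna(orig)):
                    assert pd.isna(rt) or rt == ""
                elif isinstance(orig, (int, float)):
                    assert abs(float(orig) - float(rt)) < 1e-9
                else:
                    assert str(orig) == str(rt)
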