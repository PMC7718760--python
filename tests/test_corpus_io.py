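"""Parsers for PubMed XML, gene2pubmed and annotation tables; CSV writer."""

import csv
import io
import re

import pytest

from litmine.corpus_io import (
    GenePubLink,
    parse_gene2pubmed,
    parse_interaction_table,
    parse_ortholog_table,
    parse_pathway_table,
    parse_pubmed_xml,
    write_csv,
)
from litmine.errors import FormatError


def citation(pmid, year=None, medline_date=None, headings=(), authors=(),
             version=1, title="T"):
    ys = f"<Year>{year}</Year>" if year else ""
    if medline_date:
        ys = f"<MedlineDate>{medline_date}</MedlineDate>"
    hs = "".join(
        f'<MeshHeading><DescriptorName UI="{ui}" MajorTopicYN="{mt}">{nm}'
        "</DescriptorName></MeshHeading>"
        for ui, nm, mt in headings
    )
    auth = "".join(
        f"<Author><LastName>{ln}</LastName><Initials>{ini}</Initials>"
        + (f"<AffiliationInfo><Affiliation>{aff}</Affiliation>"
           "</AffiliationInfo>" if aff else "")
        + "</Author>"
        for ln, ini, aff in authors
    )
    pmid_part = f"<PMID>{pmid}</PMID>" if pmid is not None else ""
    return (
        f'<PubmedArticle><MedlineCitation VersionID="{version}">{pmid_part}'
        f"<Article><Journal><Title>J</Title><JournalIssue><PubDate>{ys}"
        f"</PubDate></JournalIssue></Journal><ArticleTitle>{title}"
        f"</ArticleTitle>"
        + (f"<AuthorList>{auth}</AuthorList>" if auth else "")
        + f"</Article>"
        + (f"<MeshHeadingList>{hs}</MeshHeadingList>" if hs else "")
        + "</MedlineCitation></PubmedArticle>"
    )


def article_set(*parts):
    return ("<PubmedArticleSet>" + "".join(parts) + "</PubmedArticleSet>").encode()


class TestParsePubmedXml:
    def test_single_citation_field_mapping(self):
        xml = article_set(
            citation(
                101, year=2019,
                headings=[("D01", "Animals", "N"), ("D02", "Autophagy", "Y")],
                authors=[("Garcia", "M", "Boston"), ("Smith", "J", None),
                         ("Tanaka", "K", None)],
            )
        )
        records, deleted, report = parse_pubmed_xml(xml)
        assert deleted == set()
        assert report.parsed == 1 and report.skipped == 0
        (rec,) = records
        assert rec.pmid == 101 and rec.year == 2019
        assert [h.descriptor_ui for h in rec.mesh_headings] == ["D01", "D02"]
        assert rec.mesh_headings[1].major_topic is True
        assert [a.last_name for a in rec.authors] == ["Garcia", "Smith", "Tanaka"]
        assert rec.authors[0].affiliations == ("Boston",)

    def test_delete_citation_block(self):
        xml = article_set(
            citation(1, year=2000),
            "<DeleteCitation><PMID>7</PMID><PMID>9</PMID></DeleteCitation>",
        )
        _records, deleted, _report = parse_pubmed_xml(xml)
        assert deleted == {7, 9}

    @pytest.mark.parametrize(
        "medline_date",
        ["1998 Dec-1999 Jan", "Winter 1998", "1998-1999", "1998 Dec 7"],
    )
    def test_medline_date_takes_first_four_digit_token(self, medline_date):
        expected = int(re.search(r"(?<!\d)\d{4}(?!\d)", medline_date).group())
        xml = article_set(citation(1, medline_date=medline_date))
        records, _, _ = parse_pubmed_xml(xml)
        assert records[0].year == expected

    def test_unparseable_date_degrades_to_absent_year(self):
        xml = article_set(citation(1, medline_date="n.d."))
        records, _, _ = parse_pubmed_xml(xml)
        assert records[0].year is None

    def test_missing_pmid_skipped_and_counted(self):
        xml = article_set(citation(None, year=2000), citation(2, year=2001))
        records, _deleted, report = parse_pubmed_xml(xml)
        assert [r.pmid for r in records] == [2]
        assert report.parsed + report.skipped == 2
        assert report.skipped == 1

    def test_non_xml_raises_format_error_with_position(self):
        with pytest.raises(FormatError, match="line"):
            parse_pubmed_xml(b"this is not xml at all")

    def test_duplicate_pmid_last_version_wins_within_file(self):
        xml = article_set(
            citation(5, year=2000, title="old", version=1),
            citation(5, year=2000, title="new", version=2),
        )
        records, _, _ = parse_pubmed_xml(xml)
        (rec,) = records
        assert rec.title == "new" and rec.version == 2

    def test_citation_order_does_not_affect_record_set(self):
        cits = [citation(i, year=2000 + i) for i in range(1, 6)]
        fwd, _, _ = parse_pubmed_xml(article_set(*cits))
        rev, _, _ = parse_pubmed_xml(article_set(*reversed(cits)))
        assert sorted(fwd, key=lambda r: r.pmid) == sorted(rev, key=lambda r: r.pmid)

    def test_collective_name_author(self):
        xml = article_set(
            "<PubmedArticle><MedlineCitation><PMID>3</PMID><Article>"
            "<AuthorList><Author><CollectiveName>FlyBase Consortium"
            "</CollectiveName></Author></AuthorList></Article>"
            "</MedlineCitation></PubmedArticle>"
        )
        records, _, _ = parse_pubmed_xml(xml)
        (author,) = records[0].authors
        assert author.collective_name == "FlyBase Consortium"
        assert not author.is_person


class TestParseGene2Pubmed:
    HEADER = b"#tax_id\tGeneID\tPubMed_ID\n"

    def test_field_mapping(self):
        links = parse_gene2pubmed(self.HEADER + b"9606\t672\t10521298\n")
        assert links == [GenePubLink(9606, 672, 10521298)]

    def test_duplicates_collapse_to_first_occurrence(self):
        data = self.HEADER + b"9606\t672\t1\n9606\t672\t1\n"
        assert len(parse_gene2pubmed(data)) == 1

    def test_species_filter(self):
        lines = [f"7227\t{g}\t{100 + g}" for g in range(1, 5)]
        lines += [f"9606\t{g}\t{200 + g}" for g in range(1, 7)]
        data = self.HEADER + ("\n".join(lines) + "\n").encode()
        links = parse_gene2pubmed(data, species_filter={7227})
        assert len(links) == 4
        assert all(l.taxid == 7227 for l in links)

    def test_bad_line_skipped_into_report(self):
        from litmine.corpus_io import ParseReport

        report = ParseReport()
        links = parse_gene2pubmed(
            self.HEADER + b"9606\tBRCA1\t1\n9606\t672\t1\n", report=report
        )
        assert len(links) == 1
        assert report.skipped == 1 and "line 2" in report.errors[0]


class TestAnnotationTables:
    def test_pathway_rows_group_by_pathway(self):
        rows = parse_pathway_table(
            b"Notch\tGLAD\t7227\t31\nNotch\tGLAD\t7227\t42\n"
        )
        (ann,) = rows
        assert ann.pathway == "Notch" and ann.gene_ids == {31, 42}

    def test_ortholog_row(self):
        (pair,) = parse_ortholog_table(b"7227\t31\t9606\t672\t12\n")
        assert (pair.taxid_a, pair.gene_a, pair.taxid_b, pair.gene_b) == (
            7227, 31, 9606, 672,
        )
        assert pair.score == 12

    def test_ortholog_same_taxid_rejected(self):
        with pytest.raises(FormatError, match="line 1"):
            parse_ortholog_table(b"7227\t31\t7227\t42\t5\n")

    def test_interaction_same_pair_distinct_evidence(self):
        edges = parse_interaction_table(b"31\t42\tppi\n31\t42\tgenetic\n")
        assert len(edges) == 2
        assert {e.evidence for e in edges} == {"ppi", "genetic"}

    def test_bad_evidence_names_line_and_allowed_set(self):
        with pytest.raises(FormatError, match=r"line 2.*genetic.*interolog.*ppi"):
            parse_interaction_table(b"1\t2\tppi\n1\t3\tphysical\n")


class TestWriteCsv:
    def test_empty_table_writes_header_only(self):
        buf = io.StringIO()
        write_csv([], buf, columns=["a", "b"])
        assert buf.getvalue() == "a,b\r\n"

    def test_comma_in_field_is_quoted(self):
        buf = io.StringIO()
        write_csv([{"name": "Boston, MA", "n": 1}], buf)
        assert '"Boston, MA"' in buf.getvalue()

    def test_round_trip_preserves_rows_and_order(self):
        rows = [
            {"ui": "D01", "count": 3},
            {"ui": "D02", "count": 2},
            {"ui": "D03", "count": 1},
        ]
        buf = io.StringIO()
        write_csv(rows, buf)
        parsed = list(csv.DictReader(io.StringIO(buf.getvalue())))
        assert [(r["ui"], int(r["count"])) for r in parsed] == [
            ("D01", 3), ("D02", 2), ("D03", 1),
        ]
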