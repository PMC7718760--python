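"""The five search modes and ortholog mapping, against brute-force recounts."""

import pytest

from litmine.corpus_io import (
    AuthorEntry,
    GenePubLink,
    OrthologPair,
    PathwayAnnotation,
    PubRecord,
    parse_ortholog_table,
)
from litmine.errors import ParameterError
from litmine.index_builder import build_index
from litmine.query import (
    batch_publication_counts,
    co_cited,
    gene_to_mesh,
    gene_to_people,
    map_orthologs,
    mesh_to_gene,
    pathway_to_people,
    person_key,
    sort_people_by_year,
)
from oracles import manifest_co_cited, manifest_gene_to_mesh, manifest_mesh_to_gene

TAX = 7227
G1, G2, G3 = (TAX, 1), (TAX, 2), (TAX, 3)


class TestGeneToMesh:
    def test_counts_and_name_tie_break(self, t1):
        index, vocab, _ = t1
        rows = gene_to_mesh(index, vocab, G1)
        assert [(r.descriptor_name, r.pub_count) for r in rows] == [
            ("M1", 2), ("M2", 1), ("M3", 1),
        ]
        assert rows[0].pmids == {1, 2}

    def test_category_filter_keeps_matching_category_only(self, t1):
        index, vocab, _ = t1
        rows = gene_to_mesh(index, vocab, G1, category_filter="C")
        assert [(r.descriptor_name, r.pub_count) for r in rows] == [("M3", 1)]

    def test_invalid_category_letter(self, t1):
        index, vocab, _ = t1
        with pytest.raises(ParameterError, match="category"):
            gene_to_mesh(index, vocab, G1, category_filter="anatomy")

    def test_unknown_gene_empty(self, t1):
        index, vocab, _ = t1
        assert gene_to_mesh(index, vocab, (TAX, 999)) == []

    def test_counts_match_manifest_recount(self, t1):
        index, vocab, manifest = t1
        for g in (1, 2, 3):
            expect = manifest_gene_to_mesh(manifest, g)
            rows = gene_to_mesh(index, vocab, (TAX, g))
            assert {r.descriptor_ui: r.pub_count for r in rows} == expect

    def test_total_count_identity(self, t1):
        index, vocab, manifest = t1
        rows = gene_to_mesh(index, vocab, G1)
        total_headings = sum(
            len(manifest["pubs"][str(p)]["terms"])
            for p in manifest["gene_pubs"]["1"]
        )
        assert sum(r.pub_count for r in rows) == total_headings

    def test_major_topic_only_restricts_counts(self, t1):
        index, vocab, manifest = t1
        rows = gene_to_mesh(index, vocab, G1, major_topic_only=True)
        expect = manifest_gene_to_mesh(manifest, 1, major_only=True)
        assert {r.descriptor_ui: r.pub_count for r in rows} == expect

    def test_orthologs_contribute_rows_tagged_by_source(self):
        fly_pub = PubRecord(pmid=1, mesh_headings=())
        human_pub = PubRecord(pmid=2)
        records = [fly_pub, human_pub]
        links = [GenePubLink(7227, 31, 1), GenePubLink(9606, 672, 2)]
        from litmine.corpus_io import MeshHeadingRef

        records = [
            PubRecord(pmid=1, mesh_headings=(MeshHeadingRef("D01", "wings"),)),
            PubRecord(pmid=2, mesh_headings=(MeshHeadingRef("D02", "cancer"),)),
        ]
        index = build_index([(records, set())], links, {7227, 9606})
        from litmine.mesh_tree import MeshVocabulary

        table = [OrthologPair(7227, 31, 9606, 672, 12)]
        rows = gene_to_mesh(
            index, MeshVocabulary(), (7227, 31),
            include_orthologs=True, ortholog_table=table,
        )
        by_source = {r.source_gene: r.descriptor_ui for r in rows}
        assert by_source == {(7227, 31): "D01", (9606, 672): "D02"}


class TestMeshToGene:
    def test_with_children_counts(self, t1):
        index, vocab, _ = t1
        rows = mesh_to_gene(index, vocab, "D000001", include_children=True, taxid=TAX)
        assert [(r.gene_id, r.pub_count) for r in rows] == [(2, 3), (1, 2), (3, 1)]

    def test_without_children_label_tie_break(self, t1):
        index, vocab, _ = t1
        rows = mesh_to_gene(index, vocab, "D000001", include_children=False, taxid=TAX)
        assert [(r.gene_id, r.pub_count) for r in rows] == [(1, 2), (2, 2), (3, 1)]

    def test_taxid_without_links_empty(self, t1):
        index, vocab, _ = t1
        assert mesh_to_gene(index, vocab, "D000001", taxid=9606) == []

    def test_counts_match_manifest_recount(self, t1):
        index, vocab, manifest = t1
        rows = mesh_to_gene(index, vocab, "D000002", taxid=TAX)
        assert {r.gene_id: r.pub_count for r in rows} == manifest_mesh_to_gene(
            manifest, {"D000002"}
        )


class TestCoCited:
    def test_shared_publication_weights(self, t1):
        index, _, _ = t1
        rows = co_cited(index, G1)
        assert [(r.gene_id, r.weight) for r in rows] == [(2, 2), (3, 1)]
        assert rows[0].pmids == {1, 2}

    def test_weights_symmetric_across_direction(self, t1):
        index, _, manifest = t1
        w12 = {r.gene_id: r.weight for r in co_cited(index, G1)}[2]
        w21 = {r.gene_id: r.weight for r in co_cited(index, G2)}[1]
        assert w12 == w21 == manifest_co_cited(manifest, 1)[2]

    def test_gene_alone_on_papers_has_no_partners(self):
        records = [PubRecord(pmid=1)]
        index = build_index([(records, set())], [GenePubLink(TAX, 9, 1)], {TAX})
        assert co_cited(index, (TAX, 9)) == []


class TestBatch:
    def test_counts_in_input_order_with_unknowns(self, t1):
        index, _, _ = t1
        rows = batch_publication_counts(index, [G1, G2, G3, (TAX, 42)])
        assert [(r.gene_id, r.pub_count) for r in rows] == [
            (1, 3), (2, 3), (3, 2), (42, 0),
        ]
        assert rows[3].pmids == frozenset()


def person(last, initials, affil=None):
    return AuthorEntry(
        last_name=last, initials=initials,
        affiliations=(affil,) if affil else (),
    )


class TestPeople:
    def test_grouping_by_last_person_author(self):
        records = [
            PubRecord(pmid=1, year=2018,
                      authors=(person("A", "A"), person("B", "B"),
                               person("C", "C", "C's 2018 lab"))),
            PubRecord(pmid=2, year=2020,
                      authors=(person("D", "D"), person("C", "C", "C's 2020 lab"))),
        ]
        links = [GenePubLink(TAX, 1, 1), GenePubLink(TAX, 1, 2)]
        index = build_index([(records, set())], links, {TAX})
        (rec,) = gene_to_people(index, (TAX, 1))
        assert rec.person_key == "c|c"
        assert rec.pub_count == 2
        assert rec.latest_year == 2020 and rec.latest_pmid == 2
        assert rec.latest_address == "C's 2020 lab"

    def test_trailing_collective_name_skipped(self):
        records = [
            PubRecord(pmid=1, year=2019, authors=(
                person("Solo", "S"),
                AuthorEntry(collective_name="Big Consortium"),
            )),
        ]
        index = build_index([(records, set())], [GenePubLink(TAX, 1, 1)], {TAX})
        (rec,) = gene_to_people(index, (TAX, 1))
        assert rec.person_key == "solo|s"

    def test_collective_only_publication_contributes_no_record(self):
        records = [
            PubRecord(pmid=1, year=2019,
                      authors=(AuthorEntry(collective_name="Consortium"),)),
        ]
        index = build_index([(records, set())], [GenePubLink(TAX, 1, 1)], {TAX})
        assert gene_to_people(index, (TAX, 1)) == []

    def test_diacritics_fold_into_same_person(self):
        assert person_key("Łópez", "J") == person_key("Lopez", "J")

    def test_t1_gene1_people(self, t1):
        index, _, _ = t1
        recs = gene_to_people(index, G1)
        assert [(r.display_name, r.pub_count) for r in recs] == [("Gamma G", 3)]
        assert recs[0].latest_year == 2021

    def test_pathway_union_merges_and_dedups_pubs(self, t1):
        index, _, _ = t1
        pathway = PathwayAnnotation("Notch", "GLAD", TAX, frozenset({1, 2}))
        recs = pathway_to_people(index, pathway)
        by_key = {r.person_key: r for r in recs}
        # Gamma is last author of P1 (g1,g2), P2 (g1,g2,g3) and P5 (g1)
        gamma = by_key["gamma|g"]
        assert gamma.pub_count == 3          # P1, P2, P5 distinct
        assert gamma.gene_ids == {1, 2}
        # Epsilon is last author of P3 (g2 only)
        assert by_key["epsilon|e"].gene_count == 1

    def test_pathway_pub_count_bounded_by_gene_level_sum(self, t1):
        index, _, _ = t1
        pathway = PathwayAnnotation("Notch", "GLAD", TAX, frozenset({1, 2}))
        merged = pathway_to_people(index, pathway)
        per_gene = [gene_to_people(index, (TAX, g)) for g in (1, 2)]
        for rec in merged:
            gene_sum = sum(
                p.pub_count
                for recs in per_gene
                for p in recs
                if p.person_key == rec.person_key
            )
            assert rec.pub_count <= gene_sum

    def test_single_gene_pathway_reduces_to_gene_search(self, t1):
        index, _, _ = t1
        pathway = PathwayAnnotation("solo", "GLAD", TAX, frozenset({2}))
        a = [(r.person_key, r.pub_count) for r in pathway_to_people(index, pathway)]
        b = [(r.person_key, r.pub_count) for r in gene_to_people(index, G2)]
        assert a == b

    def test_empty_pathway_rejected(self, t1):
        index, _, _ = t1
        with pytest.raises(ParameterError):
            pathway_to_people(
                index, PathwayAnnotation("void", "GLAD", TAX, frozenset())
            )

    def test_resort_by_year(self):
        records = [
            PubRecord(pmid=1, year=2010, authors=(person("Old", "O"),)),
            PubRecord(pmid=2, year=2010, authors=(person("Old", "O"),)),
            PubRecord(pmid=3, year=2021, authors=(person("New", "N"),)),
        ]
        links = [GenePubLink(TAX, 1, p) for p in (1, 2, 3)]
        index = build_index([(records, set())], links, {TAX})
        default = gene_to_people(index, (TAX, 1))
        assert [r.person_key for r in default] == ["old|o", "new|n"]
        by_year = sort_people_by_year(default)
        assert [r.person_key for r in by_year] == ["new|n", "old|o"]


class TestMapOrthologs:
    TABLE = b"7227\t31\t9606\t672\t12\n7227\t31\t9606\t673\t3\n7227\t42\t9606\t675\t9\n"

    def test_simple_mapping(self):
        table = parse_ortholog_table(self.TABLE)
        rows = map_orthologs([31], table, 9606)
        assert [(r.source_gene, r.target_gene, r.score) for r in rows] == [
            (31, 672, 12.0), (31, 673, 3.0),
        ]

    def test_min_score_threshold(self):
        table = parse_ortholog_table(b"7227\t31\t9606\t672\t12\n")
        assert map_orthologs([31], table, 9606, min_score=15) == []

    def test_reverse_direction_applies(self):
        table = parse_ortholog_table(self.TABLE)
        rows = map_orthologs([672], table, 7227)
        assert [(r.source_gene, r.target_gene) for r in rows] == [(672, 31)]

    def test_absent_target_taxid_warns_and_returns_empty(self):
        table = parse_ortholog_table(self.TABLE)
        with pytest.warns(UserWarning, match="10090"):
            assert map_orthologs([31], table, 10090) == []
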