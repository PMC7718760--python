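"""Merge parsed batches into a queryable, gene-filtered corpus index.

The MEDLINE distribution model is a yearly baseline plus incremental update
files; an update may *revise* a citation (same PMID, possibly a higher
``VersionID``) or *delete* it (``DeleteCitation``).  :func:`build_index`
replays batches oldest-first with last-version-wins semantics and then keeps
only publications linked to at least one gene of an admitted species — the
filter that turns the raw literature into a gene-centric corpus.

The resulting :class:`CorpusIndex` holds bidirectional gene <-> PMID and
MeSH <-> PMID maps and serializes to a single-file SQLite store so query
commands can run without re-parsing the sources.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus_io import AuthorEntry, GenePubLink, MeshHeadingRef, PubRecord
from .errors import MeshLookupError
from .mesh_tree import MeshDescriptor, MeshVocabulary, descendants

#: Default admitted species: human plus nine major model organisms
#: (mouse, rat, zebrafish, frog, fly, worm, budding and fission yeast,
#: Arabidopsis).  Configurable — pass any taxid set to build_index.
DEFAULT_SPECIES = frozenset(
    {9606, 10090, 10116, 7955, 8364, 7227, 6239, 559292, 4896, 3702}
)

Gene = tuple[int, int]  # (taxid, gene_id)


@dataclass
class BuildReport:
    """Counts accumulated while building an index."""

    records_seen: int = 0        # records across all batches (pre-merge)
    records_merged: int = 0      # distinct PMIDs after last-version-wins
    records_deleted: int = 0     # PMIDs removed by DeleteCitation
    records_filtered: int = 0    # merged records dropped for having no gene link
    links_kept: int = 0
    links_dropped: int = 0       # links to unretained PMIDs
    dangling_links: int = 0      # links to PMIDs absent from all batches


@dataclass
class CorpusIndex:
    pub_by_pmid: dict[int, PubRecord] = field(default_factory=dict)
    pubs_by_gene: dict[Gene, set[int]] = field(default_factory=dict)
    genes_by_pub: dict[int, set[Gene]] = field(default_factory=dict)
    pubs_by_mesh: dict[str, set[int]] = field(default_factory=dict)
    pubs_by_mesh_major: dict[str, set[int]] = field(default_factory=dict)
    species: set[int] = field(default_factory=set)
    report: BuildReport = field(default_factory=BuildReport)

    def genes_of_taxid(self, taxid: int) -> set[Gene]:
        return {g for g in self.pubs_by_gene if g[0] == taxid}


def build_index(
    record_batches: Sequence[tuple[Iterable[PubRecord], set[int]]],
    links: Iterable[GenePubLink],
    species: Iterable[int] = DEFAULT_SPECIES,
) -> CorpusIndex:
    """Build a :class:`CorpusIndex` from ordered record batches and gene links.

    *record_batches* is ordered oldest-first (baseline before updates); each
    element is ``(records, deleted_pmids)``.  Per PMID the record from the
    latest batch wins, ties broken by higher citation version; a PMID listed
    in any later batch's deleted set is absent from the result.  Only
    publications linked to >= 1 gene of an admitted species survive.
    """
    species = set(species)
    merged: dict[int, tuple[int, int, PubRecord]] = {}  # pmid -> (batch, version, rec)
    report = BuildReport()
    deleted_total: set[int] = set()
    for batch_no, (records, deleted) in enumerate(record_batches):
        for rec in records:
            report.records_seen += 1
            prev = merged.get(rec.pmid)
            if prev is None or (batch_no, rec.version) >= prev[:2]:
                merged[rec.pmid] = (batch_no, rec.version, rec)
            deleted_total.discard(rec.pmid)  # re-issued after deletion
        for pmid in deleted:
            if pmid in merged:
                del merged[pmid]
            deleted_total.add(pmid)
    report.records_merged = len(merged)
    report.records_deleted = len(deleted_total)

    index = CorpusIndex(species=species, report=report)
    genes_by_pub: dict[int, set[Gene]] = {}
    for link in links:
        if link.taxid not in species:
            continue
        if link.pmid not in merged:
            if link.pmid in deleted_total:
                report.links_dropped += 1
            else:
                report.dangling_links += 1
            continue
        genes_by_pub.setdefault(link.pmid, set()).add((link.taxid, link.gene_id))
        report.links_kept += 1

    for pmid, (_b, _v, rec) in merged.items():
        genes = genes_by_pub.get(pmid)
        if not genes:
            report.records_filtered += 1
            continue
        index.pub_by_pmid[pmid] = rec
        index.genes_by_pub[pmid] = genes
        for g in genes:
            index.pubs_by_gene.setdefault(g, set()).add(pmid)
        for h in rec.mesh_headings:
            index.pubs_by_mesh.setdefault(h.descriptor_ui, set()).add(pmid)
            if h.major_topic:
                index.pubs_by_mesh_major.setdefault(h.descriptor_ui, set()).add(pmid)
    return index


def gene_pubs(index: CorpusIndex, taxid: int, gene_id: int) -> set[int]:
    """PMIDs linked to one gene; unknown genes yield the empty set."""
    return set(index.pubs_by_gene.get((taxid, gene_id), ()))


def mesh_pubs(
    index: CorpusIndex,
    vocab: MeshVocabulary,
    ui: str,
    include_descendants: bool = False,
    major_only: bool = False,
) -> set[int]:
    """PMIDs annotated with *ui* (optionally expanded to its subtree)."""
    if ui not in vocab:
        raise MeshLookupError(ui)
    uis = {ui}
    if include_descendants:
        uis |= descendants(vocab, ui)
    table = index.pubs_by_mesh_major if major_only else index.pubs_by_mesh
    out: set[int] = set()
    for u in uis:
        out |= table.get(u, set())
    return out


# ---------------------------------------------------------------------------
# SQLite persistence (single-file embedded store)
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE species (taxid INTEGER PRIMARY KEY);
CREATE TABLE pubs (
    pmid INTEGER PRIMARY KEY, year INTEGER, title TEXT, journal TEXT,
    version INTEGER NOT NULL
);
CREATE TABLE headings (
    pmid INTEGER NOT NULL, pos INTEGER NOT NULL,
    ui TEXT NOT NULL, name TEXT NOT NULL, major INTEGER NOT NULL,
    PRIMARY KEY (pmid, pos)
);
CREATE TABLE authors (
    pmid INTEGER NOT NULL, pos INTEGER NOT NULL,
    last TEXT, fore TEXT, initials TEXT, collective TEXT,
    PRIMARY KEY (pmid, pos)
);
CREATE TABLE affiliations (
    pmid INTEGER NOT NULL, author_pos INTEGER NOT NULL, pos INTEGER NOT NULL,
    text TEXT NOT NULL,
    PRIMARY KEY (pmid, author_pos, pos)
);
CREATE TABLE gene_links (
    taxid INTEGER NOT NULL, gene_id INTEGER NOT NULL, pmid INTEGER NOT NULL,
    PRIMARY KEY (taxid, gene_id, pmid)
);
CREATE TABLE mesh_descriptors (
    ui TEXT PRIMARY KEY, name TEXT NOT NULL
);
CREATE TABLE mesh_trees (
    tree TEXT PRIMARY KEY, ui TEXT NOT NULL
);
CREATE INDEX idx_links_pmid ON gene_links (pmid);
CREATE INDEX idx_headings_ui ON headings (ui);
"""


def save_index(
    index: CorpusIndex,
    path: str,
    vocab: Optional[MeshVocabulary] = None,
) -> None:
    """Serialize an index (and optionally its vocabulary) to a SQLite file."""
    con = sqlite3.connect(path)
    try:
        con.executescript("PRAGMA journal_mode=MEMORY;")
        con.executescript(_SCHEMA)
        con.execute("INSERT INTO meta VALUES ('format', '1')")
        con.executemany(
            "INSERT INTO species VALUES (?)", [(t,) for t in sorted(index.species)]
        )
        for pmid in sorted(index.pub_by_pmid):
            rec = index.pub_by_pmid[pmid]
            con.execute(
                "INSERT INTO pubs VALUES (?,?,?,?,?)",
                (rec.pmid, rec.year, rec.title, rec.journal, rec.version),
            )
            for i, h in enumerate(rec.mesh_headings):
                con.execute(
                    "INSERT INTO headings VALUES (?,?,?,?,?)",
                    (pmid, i, h.descriptor_ui, h.descriptor_name,
                     int(h.major_topic)),
                )
            for i, a in enumerate(rec.authors):
                con.execute(
                    "INSERT INTO authors VALUES (?,?,?,?,?,?)",
                    (pmid, i, a.last_name, a.fore_name, a.initials,
                     a.collective_name),
                )
                for j, aff in enumerate(a.affiliations):
                    con.execute(
                        "INSERT INTO affiliations VALUES (?,?,?,?)",
                        (pmid, i, j, aff),
                    )
        for (taxid, gene_id), pmids in sorted(index.pubs_by_gene.items()):
            con.executemany(
                "INSERT INTO gene_links VALUES (?,?,?)",
                [(taxid, gene_id, p) for p in sorted(pmids)],
            )
        if vocab is not None:
            for ui in sorted(vocab.descriptors):
                d = vocab.descriptors[ui]
                con.execute(
                    "INSERT INTO mesh_descriptors VALUES (?,?)", (d.ui, d.name)
                )
                con.executemany(
                    "INSERT INTO mesh_trees VALUES (?,?)",
                    [(t, d.ui) for t in sorted(d.tree_numbers)],
                )
        con.commit()
    finally:
        con.close()


def load_index(path: str) -> tuple[CorpusIndex, Optional[MeshVocabulary]]:
    """Load an index (and vocabulary, if stored) from a SQLite file."""
    con = sqlite3.connect(path)
    try:
        index = CorpusIndex()
        index.species = {t for (t,) in con.execute("SELECT taxid FROM species")}
        headings: dict[int, list[MeshHeadingRef]] = {}
        for pmid, _pos, ui, name, major in con.execute(
            "SELECT pmid, pos, ui, name, major FROM headings ORDER BY pmid, pos"
        ):
            headings.setdefault(pmid, []).append(
                MeshHeadingRef(ui, name, bool(major))
            )
        affs: dict[tuple[int, int], list[str]] = {}
        for pmid, apos, _pos, text in con.execute(
            "SELECT pmid, author_pos, pos, text FROM affiliations "
            "ORDER BY pmid, author_pos, pos"
        ):
            affs.setdefault((pmid, apos), []).append(text)
        authors: dict[int, list[AuthorEntry]] = {}
        for pmid, pos, last, fore, initials, collective in con.execute(
            "SELECT pmid, pos, last, fore, initials, collective FROM authors "
            "ORDER BY pmid, pos"
        ):
            authors.setdefault(pmid, []).append(
                AuthorEntry(
                    last_name=last, fore_name=fore, initials=initials,
                    collective_name=collective,
                    affiliations=tuple(affs.get((pmid, pos), ())),
                )
            )
        for pmid, year, title, journal, version in con.execute(
            "SELECT pmid, year, title, journal, version FROM pubs"
        ):
            rec = PubRecord(
                pmid=pmid, year=year, title=title, journal=journal,
                mesh_headings=tuple(headings.get(pmid, ())),
                authors=tuple(authors.get(pmid, ())),
                version=version,
            )
            index.pub_by_pmid[pmid] = rec
            for h in rec.mesh_headings:
                index.pubs_by_mesh.setdefault(h.descriptor_ui, set()).add(pmid)
                if h.major_topic:
                    index.pubs_by_mesh_major.setdefault(
                        h.descriptor_ui, set()
                    ).add(pmid)
        for taxid, gene_id, pmid in con.execute(
            "SELECT taxid, gene_id, pmid FROM gene_links"
        ):
            g = (taxid, gene_id)
            index.pubs_by_gene.setdefault(g, set()).add(pmid)
            index.genes_by_pub.setdefault(pmid, set()).add(g)

        vocab: Optional[MeshVocabulary] = None
        desc_rows = list(
            con.execute("SELECT ui, name FROM mesh_descriptors ORDER BY ui")
        )
        if desc_rows:
            trees: dict[str, set[str]] = {}
            for tree, ui in con.execute("SELECT tree, ui FROM mesh_trees"):
                trees.setdefault(ui, set()).add(tree)
            vocab = MeshVocabulary()
            for ui, name in desc_rows:
                vocab.add(
                    MeshDescriptor(
                        ui=ui, name=name,
                        tree_numbers=frozenset(trees.get(ui, ())),
                    )
                )
        return index, vocab
    finally:
        con.close()
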