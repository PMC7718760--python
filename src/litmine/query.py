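"""Search modes over a built corpus index.

Five searches mirror a gene-centric literature workflow:

* **gene -> MeSH**: which subjects is this gene's literature about?
* **MeSH -> gene**: which genes does the literature on this subject involve?
* **co-citation**: which genes share publications with this one?
* **batch**: publication counts for a whole gene list,
* **people**: last authors (the supervising-investigator proxy) of the
  literature on a gene or pathway,

plus ortholog mapping of gene lists between species.  Every result list has
a total, documented sort order so CSV exports are byte-stable.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .corpus_io import OrthologPair, PathwayAnnotation, PubRecord
from .errors import MeshLookupError, ParameterError
from .index_builder import CorpusIndex, Gene, gene_pubs, mesh_pubs
from .mesh_tree import MeshVocabulary


def gene_label(gene: Gene, symbols: Optional[dict[Gene, str]] = None) -> str:
    """Display label: symbol when a symbol table is given, else taxid:gene_id."""
    if symbols and gene in symbols:
        return symbols[gene]
    return f"{gene[0]}:{gene[1]}"


# ---------------------------------------------------------------------------
# Result rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneMeshRow:
    descriptor_ui: str
    descriptor_name: str
    pub_count: int
    pmids: frozenset[int]
    source_gene: Gene  # the input gene or the ortholog contributing the papers

    CSV_COLUMNS = (
        "descriptor_ui", "descriptor_name", "pub_count", "pmids", "source_gene",
    )


@dataclass(frozen=True)
class MeshGeneRow:
    taxid: int
    gene_id: int
    label: str
    pub_count: int
    pmids: frozenset[int]

    CSV_COLUMNS = ("taxid", "gene_id", "label", "pub_count", "pmids")


@dataclass(frozen=True)
class CoCitationRow:
    taxid: int
    gene_id: int
    label: str
    weight: int  # number of shared publications
    pmids: frozenset[int]

    CSV_COLUMNS = ("taxid", "gene_id", "label", "weight", "pmids")


@dataclass(frozen=True)
class BatchCountRow:
    taxid: int
    gene_id: int
    pub_count: int
    pmids: frozenset[int]

    CSV_COLUMNS = ("taxid", "gene_id", "pub_count", "pmids")


@dataclass(frozen=True)
class PersonRecord:
    """Last-author aggregate over a search scope (one gene or a pathway)."""

    person_key: str          # normalized "lastname|initials"
    display_name: str
    pub_count: int
    gene_ids: frozenset[int]  # scope genes the person published on
    latest_year: Optional[int]
    latest_pmid: int
    latest_address: Optional[str]
    pmids: frozenset[int]

    @property
    def gene_count(self) -> int:
        return len(self.gene_ids)

    CSV_COLUMNS = (
        "person_key", "display_name", "pub_count", "gene_ids",
        "latest_year", "latest_pmid", "latest_address",
    )


@dataclass(frozen=True)
class OrthologRow:
    source_gene: int
    target_gene: int
    score: float

    CSV_COLUMNS = ("source_gene", "target_gene", "score")


# ---------------------------------------------------------------------------
# gene -> MeSH
# ---------------------------------------------------------------------------

def _ortholog_partners(
    gene: Gene, ortholog_table: Iterable[OrthologPair]
) -> set[Gene]:
    """Genes paired with *gene* in either stored direction."""
    taxid, gid = gene
    partners: set[Gene] = set()
    for p in ortholog_table:
        if (p.taxid_a, p.gene_a) == (taxid, gid):
            partners.add((p.taxid_b, p.gene_b))
        elif (p.taxid_b, p.gene_b) == (taxid, gid):
            partners.add((p.taxid_a, p.gene_a))
    return partners


def gene_to_mesh(
    index: CorpusIndex,
    vocab: MeshVocabulary,
    gene: Gene,
    include_orthologs: bool = False,
    ortholog_table: Iterable[OrthologPair] = (),
    category_filter: Optional[str] = None,
    major_topic_only: bool = False,
) -> list[GeneMeshRow]:
    """Per-descriptor publication counts for a gene (and optionally its orthologs).

    Each row reports its contributing gene in ``source_gene`` so results from
    the input gene and from orthologs remain separable.  *category_filter*
    keeps only descriptors whose category letters contain the given letter
    (e.g. ``"A"`` for anatomy).  Rows sort by pub_count descending, ties by
    descriptor name then source gene.
    """
    if category_filter is not None and not (
        len(category_filter) == 1 and category_filter.isalpha()
        and category_filter.isupper()
    ):
        raise ParameterError(
            f"category letter must be a single uppercase letter, "
            f"got {category_filter!r}"
        )
    sources: list[Gene] = [gene]
    if include_orthologs:
        sources.extend(sorted(_ortholog_partners(gene, ortholog_table)))
    rows: list[GeneMeshRow] = []
    for src in sources:
        counts: dict[str, set[int]] = {}
        names: dict[str, str] = {}
        for pmid in gene_pubs(index, *src):
            rec = index.pub_by_pmid[pmid]
            for h in rec.mesh_headings:
                if major_topic_only and not h.major_topic:
                    continue
                counts.setdefault(h.descriptor_ui, set()).add(pmid)
                names[h.descriptor_ui] = h.descriptor_name
        for ui, pmids in counts.items():
            if category_filter is not None:
                if ui not in vocab:
                    continue
                if category_filter not in vocab.get(ui).category:
                    continue
            name = vocab.name_of(ui) if ui in vocab else names[ui]
            rows.append(
                GeneMeshRow(
                    descriptor_ui=ui,
                    descriptor_name=name,
                    pub_count=len(pmids),
                    pmids=frozenset(pmids),
                    source_gene=src,
                )
            )
    rows.sort(key=lambda r: (-r.pub_count, r.descriptor_name, r.source_gene))
    return rows


# ---------------------------------------------------------------------------
# MeSH -> gene
# ---------------------------------------------------------------------------

def mesh_to_gene(
    index: CorpusIndex,
    vocab: MeshVocabulary,
    ui: str,
    include_children: bool = False,
    taxid: Optional[int] = None,
    symbols: Optional[dict[Gene, str]] = None,
    major_topic_only: bool = False,
) -> list[MeshGeneRow]:
    """Genes of a species linked to the publications carrying a MeSH term.

    *include_children* expands the term to its whole subtree (all more
    specific descendants).  Rows sort by pub_count descending, ties by label.
    """
    pmids = mesh_pubs(
        index, vocab, ui,
        include_descendants=include_children, major_only=major_topic_only,
    )
    counts: dict[Gene, set[int]] = {}
    for pmid in pmids:
        for g in index.genes_by_pub.get(pmid, ()):
            if taxid is not None and g[0] != taxid:
                continue
            counts.setdefault(g, set()).add(pmid)
    rows = [
        MeshGeneRow(
            taxid=g[0], gene_id=g[1], label=gene_label(g, symbols),
            pub_count=len(ps), pmids=frozenset(ps),
        )
        for g, ps in counts.items()
    ]
    rows.sort(key=lambda r: (-r.pub_count, r.label, r.gene_id))
    return rows


# ---------------------------------------------------------------------------
# co-citation
# ---------------------------------------------------------------------------

def co_cited(
    index: CorpusIndex,
    gene: Gene,
    same_species_only: bool = True,
    symbols: Optional[dict[Gene, str]] = None,
) -> list[CoCitationRow]:
    """Genes sharing >= 1 publication with *gene*, weighted by shared count.

    Weights are symmetric across query direction.  Sorted by weight
    descending, ties by label.
    """
    shared: dict[Gene, set[int]] = {}
    for pmid in gene_pubs(index, *gene):
        for g in index.genes_by_pub.get(pmid, ()):
            if g == gene:
                continue
            if same_species_only and g[0] != gene[0]:
                continue
            shared.setdefault(g, set()).add(pmid)
    rows = [
        CoCitationRow(
            taxid=g[0], gene_id=g[1], label=gene_label(g, symbols),
            weight=len(ps), pmids=frozenset(ps),
        )
        for g, ps in shared.items()
    ]
    rows.sort(key=lambda r: (-r.weight, r.label, r.gene_id))
    return rows


# ---------------------------------------------------------------------------
# batch search
# ---------------------------------------------------------------------------

def batch_publication_counts(
    index: CorpusIndex, gene_list: Sequence[Gene]
) -> list[BatchCountRow]:
    """One row per input gene, in input order; unknown genes count 0."""
    rows = []
    for g in gene_list:
        pmids = gene_pubs(index, *g)
        rows.append(
            BatchCountRow(
                taxid=g[0], gene_id=g[1],
                pub_count=len(pmids), pmids=frozenset(pmids),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# people search
# ---------------------------------------------------------------------------

# letters whose diacritic is not a combining mark, so NFKD leaves them intact
_STROKED = str.maketrans(
    {"ł": "l", "Ł": "L", "ø": "o", "Ø": "O", "đ": "d", "Đ": "D",
     "ß": "ss", "æ": "ae", "Æ": "AE", "œ": "oe", "Œ": "OE"}
)


def person_key(last_name: str, initials: Optional[str]) -> str:
    """Normalized author identity: diacritic-folded lowercased lastname|initials.

    Homonymous scientists collapse under this key; disambiguation beyond the
    name (e.g. ORCID) is out of scope.
    """
    def fold(s: str) -> str:
        decomposed = unicodedata.normalize("NFKD", s.translate(_STROKED))
        return "".join(c for c in decomposed if not unicodedata.combining(c))

    return f"{fold(last_name).lower()}|{fold(initials or '').lower()}"


def last_person_author(record: PubRecord):
    """Last element of the author list that is a person (trailing consortium
    entries skipped); None when no person author exists."""
    for author in reversed(record.authors):
        if author.is_person:
            return author
    return None


def _people_from_pubs(
    index: CorpusIndex,
    pub_genes: dict[int, set[int]],
) -> list[PersonRecord]:
    """Group publications by last person author.

    *pub_genes* maps each pmid to the scope genes it contributes (for
    gene-level search this is the single input gene).
    """
    groups: dict[str, dict] = {}
    for pmid, scope_genes in pub_genes.items():
        rec = index.pub_by_pmid[pmid]
        author = last_person_author(rec)
        if author is None:
            continue  # consortium-only or authorless publications drop out
        key = person_key(author.last_name, author.initials)
        g = groups.setdefault(
            key, {"pmids": set(), "genes": set(), "latest": None},
        )
        g["pmids"].add(pmid)
        g["genes"] |= scope_genes
        # recency: year first (missing year sorts lowest), larger pmid breaks ties
        rank = (rec.year if rec.year is not None else -1, pmid)
        if g["latest"] is None or rank > g["latest"][0]:
            display = author.last_name + (
                f" {author.initials}" if author.initials else ""
            )
            address = author.affiliations[0] if author.affiliations else None
            g["latest"] = (rank, rec, display, address)
    records = []
    for key, g in groups.items():
        _rank, rec, display, address = g["latest"]
        records.append(
            PersonRecord(
                person_key=key,
                display_name=display,
                pub_count=len(g["pmids"]),
                gene_ids=frozenset(g["genes"]),
                latest_year=rec.year,
                latest_pmid=rec.pmid,
                latest_address=address,
                pmids=frozenset(g["pmids"]),
            )
        )
    records.sort(
        key=lambda p: (
            -p.pub_count,
            -(p.latest_year if p.latest_year is not None else -1),
            p.person_key,
        )
    )
    return records


def gene_to_people(index: CorpusIndex, gene: Gene) -> list[PersonRecord]:
    """Last authors of all publications linked to a gene, with publication
    counts and the year/address of each person's most recent paper."""
    pub_genes = {pmid: {gene[1]} for pmid in gene_pubs(index, *gene)}
    return _people_from_pubs(index, pub_genes)


def pathway_to_people(
    index: CorpusIndex, pathway: PathwayAnnotation
) -> list[PersonRecord]:
    """Last authors across a pathway's genes, merged per person.

    ``pub_count`` counts distinct publications (a paper covering two pathway
    genes counts once); ``gene_ids`` are the pathway genes the person has
    published on.
    """
    if not pathway.gene_ids:
        raise ParameterError(f"pathway {pathway.pathway!r} has no genes")
    pub_genes: dict[int, set[int]] = {}
    for gid in pathway.gene_ids:
        for pmid in gene_pubs(index, pathway.taxid, gid):
            pub_genes.setdefault(pmid, set()).add(gid)
    return _people_from_pubs(index, pub_genes)


def sort_people_by_year(records: Sequence[PersonRecord]) -> list[PersonRecord]:
    """Alternative ordering: most recent publication first."""
    return sorted(
        records,
        key=lambda p: (
            -(p.latest_year if p.latest_year is not None else -1),
            -p.pub_count,
            p.person_key,
        ),
    )


# ---------------------------------------------------------------------------
# ortholog mapping of gene lists
# ---------------------------------------------------------------------------

def map_orthologs(
    gene_list: Sequence[int],
    ortholog_table: Iterable[OrthologPair],
    target_taxid: int,
    min_score: Optional[float] = None,
) -> list[OrthologRow]:
    """Map a gene list to orthologs in *target_taxid*.

    Pairs apply in both stored directions; a source gene may map to several
    targets and vice versa.  Rows sort by source gene, then score descending,
    then target gene.
    """
    table = list(ortholog_table)
    if not any(target_taxid in (p.taxid_a, p.taxid_b) for p in table):
        warnings.warn(
            f"target taxid {target_taxid} absent from ortholog table",
            stacklevel=2,
        )
        return []
    wanted = set(gene_list)
    out: set[tuple[int, int, float]] = set()
    for p in table:
        if p.taxid_b == target_taxid and p.gene_a in wanted:
            out.add((p.gene_a, p.gene_b, p.score))
        if p.taxid_a == target_taxid and p.gene_b in wanted:
            out.add((p.gene_b, p.gene_a, p.score))
    rows = [OrthologRow(*t) for t in out]
    rows = [r for r in rows if min_score is None or r.score >= min_score]
    rows.sort(key=lambda r: (r.source_gene, -r.score, r.target_gene))
    return rows
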