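"""Seeded generator of a complete synthetic input bundle.

Emits, as real on-disk files in the standard distribution formats, everything
the pipeline consumes: a PubMed-style baseline XML, one update XML carrying
revisions and a ``DeleteCitation`` block, a gene2pubmed TSV, a MeSH
descriptor XML with a multi-level tree in several categories, and
pathway/ortholog/interaction tables — plus a ground-truth manifest (JSON)
that exactly describes the emitted corpus, so every query result can be
recounted independently of the index.

Identical config + seed produces byte-identical bundles; all randomness
flows through one seeded ``random.Random`` instance.  Optional *planting*
hooks insert known signal: a MeSH term preferentially attached to the
publications of a designated gene set (for enrichment recovery tests) and a
gene clique with an elevated co-publication rate (for co-citation tests).

The generator emulates the structural features the pipeline depends on —
identifier links, heading lists, author order, revision/deletion semantics,
skewed term popularity — not realistic titles or abstracts; no free text is
mined.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from . import corpus_io
from .corpus_io import parse_gene2pubmed, parse_pubmed_xml
from .index_builder import CorpusIndex, build_index
from .mesh_tree import MeshVocabulary, parse_mesh_xml


@dataclass(frozen=True)
class PlantedEnrichment:
    """A term planted with known gene-level association rates.

    Because the enrichment test counts *genes*, the planted probabilities
    are per gene: each gene of the designated list becomes term-associated
    with probability *p_inside*, each background gene with *p_outside*.
    The generator realizes the designation by attaching the term to
    publications whose gene sets lie inside the designated set, forcing one
    attachment (with minimal spill-over to co-published genes) for
    designated genes that would otherwise lack coverage.  The manifest
    records the realized associations exactly.
    """

    n_list_genes: int = 10
    p_inside: float = 0.8
    p_outside: float = 0.1


@dataclass(frozen=True)
class PlantedCoCitation:
    """A gene clique whose members co-publish at the given rate."""

    n_genes: int = 4
    rate: float = 0.3


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_pubs: int = 200
    n_genes: int = 100
    n_terms: int = 50
    n_authors: int = 30
    taxid: int = 7227
    ortholog_taxid: int = 9606
    year_range: tuple[int, int] = (2000, 2020)
    missing_year_fraction: float = 0.05
    term_popularity: float = 1.2     # power-law exponent over descriptor ranks
    major_topic_fraction: float = 0.3
    planted_enrichment: Optional[PlantedEnrichment] = None
    planted_cocite: Optional[PlantedCoCitation] = None
    deletion_fraction: float = 0.0
    revision_fraction: float = 0.0

    def __post_init__(self):
        for name in ("n_pubs", "n_genes", "n_terms", "n_authors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "missing_year_fraction", "major_topic_fraction",
            "deletion_fraction", "revision_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class BundlePaths:
    baseline: Path
    updates: list[Path]
    gene2pubmed: Path
    mesh: Path
    pathways: Path
    orthologs: Path
    interactions: Path
    manifest: Path


# ---------------------------------------------------------------------------
# internal pub model used during generation
# ---------------------------------------------------------------------------

@dataclass
class _Pub:
    pmid: int
    year: Optional[int]
    title: str
    genes: list[int]
    terms: list[str]            # descriptor UIs, ordered
    major: set[str]             # subset of terms flagged as major topic
    authors: list[dict]         # {"last":..., "fore":..., "initials":..., "affil":...}
    version: int = 1


def _make_vocab(rng: random.Random, n_terms: int) -> list[dict]:
    """Descriptor dicts {ui, name, trees}; >= 3 levels in >= 2 categories."""
    terms: list[dict] = []
    counter = [0]

    def new_term(trees: list[str]) -> dict:
        counter[0] += 1
        ui = f"D{counter[0]:06d}"
        t = {"ui": ui, "name": f"T{counter[0]:03d}", "trees": trees}
        terms.append(t)
        return t

    # guaranteed depth-3 chains in two categories
    for letter in ("A", "C"):
        root = new_term([f"{letter}01"])
        child = new_term([root["trees"][0] + ".100"])
        new_term([child["trees"][0] + ".100"])
    new_term(["G01"])  # third category root
    attach_counter: dict[str, int] = {}
    while len(terms) < n_terms:
        parent = rng.choice(terms)
        ptree = parent["trees"][0]
        if ptree.count(".") >= 3:  # cap depth at 4 levels
            continue
        attach_counter[ptree] = attach_counter.get(ptree, 0) + 101
        new_term([f"{ptree}.{attach_counter[ptree]:03d}"])
    return terms[:n_terms]


def _weighted_sample(
    rng: random.Random, items: Sequence, weights: Sequence[float], k: int
) -> list:
    """Sample up to k distinct items by repeated weighted draws."""
    chosen: list = []
    pool = list(range(len(items)))
    w = list(weights)
    for _ in range(min(k, len(pool))):
        total = sum(w[i] for i in pool)
        r = rng.random() * total
        acc = 0.0
        for idx, i in enumerate(pool):
            acc += w[i]
            if acc >= r:
                chosen.append(items[i])
                pool.pop(idx)
                break
    return chosen


def _generate_pubs(config: FixtureConfig, rng: random.Random,
                   vocab_terms: list[dict]) -> tuple[list[_Pub], Optional[str], list[int], list[int]]:
    gene_ids = list(range(1, config.n_genes + 1))
    planted_term: Optional[str] = None
    planted_genes: list[int] = []
    free_terms = list(vocab_terms)
    if config.planted_enrichment is not None:
        # dedicate a non-root descriptor to the planted signal
        planted = next(t for t in free_terms if "." in t["trees"][0])
        planted_term = planted["ui"]
        free_terms = [t for t in free_terms if t["ui"] != planted_term]
        planted_genes = gene_ids[: config.planted_enrichment.n_list_genes]
    clique: list[int] = []
    if config.planted_cocite is not None:
        clique = gene_ids[-config.planted_cocite.n_genes:]
    term_weights = [
        (rank + 1) ** (-config.term_popularity)
        for rank in range(len(free_terms))
    ]
    authors = [
        {
            "last": f"Lastname{j:02d}",
            "fore": f"Fore{j:02d}",
            "initials": chr(65 + j % 26),
            "affil": f"Dept {j % 9}, University {j % 7}, City {j % 5}",
        }
        for j in range(config.n_authors)
    ]
    pubs: list[_Pub] = []
    for i in range(config.n_pubs):
        pmid = 100001 + i
        year: Optional[int] = None
        if rng.random() >= config.missing_year_fraction:
            year = rng.randint(*config.year_range)
        if clique and rng.random() < config.planted_cocite.rate:
            genes = rng.sample(clique, k=min(len(clique), rng.choice([2, 2, 3])))
        else:
            n_g = rng.choices([1, 2, 3], weights=[0.5, 0.35, 0.15])[0]
            genes = rng.sample(gene_ids, k=n_g)
        n_t = rng.choices([0, 1, 2, 3, 4],
                          weights=[0.05, 0.25, 0.35, 0.25, 0.10])[0]
        terms = [
            t["ui"]
            for t in _weighted_sample(rng, free_terms, term_weights, n_t)
        ]
        major = {t for t in terms if rng.random() < config.major_topic_fraction}
        n_a = rng.choices([1, 2, 3, 4], weights=[0.2, 0.35, 0.3, 0.15])[0]
        pub_authors = [dict(a) for a in rng.sample(authors, k=n_a)]
        pubs.append(
            _Pub(
                pmid=pmid, year=year, title=f"Synthetic study {pmid}",
                genes=sorted(genes), terms=terms, major=major,
                authors=pub_authors,
            )
        )
    if planted_term is not None:
        _plant_term(config, rng, pubs, planted_term, planted_genes, gene_ids)
    return pubs, planted_term, planted_genes, clique


def _plant_term(
    config: FixtureConfig,
    rng: random.Random,
    pubs: list[_Pub],
    planted_term: str,
    planted_genes: list[int],
    gene_ids: list[int],
) -> None:
    """Attach the planted term so gene-level association tracks the designated
    per-gene rates (p_inside for list genes, p_outside for the rest)."""
    cfg = config.planted_enrichment
    inside = set(planted_genes)
    designated = {
        g for g in gene_ids
        if rng.random() < (cfg.p_inside if g in inside else cfg.p_outside)
    }
    covered: set[int] = set()
    for pub in pubs:
        if pub.genes and set(pub.genes) <= designated:
            pub.terms.append(planted_term)
            covered.update(pub.genes)
    # designated genes still uncovered get one forced attachment on the
    # publication that spills onto the fewest non-designated co-genes
    pubs_of: dict[int, list[_Pub]] = {}
    for pub in pubs:
        for g in pub.genes:
            pubs_of.setdefault(g, []).append(pub)
    for g in sorted(designated - covered):
        candidates = [p for p in pubs_of.get(g, ()) if planted_term not in p.terms]
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda p: (sum(1 for x in p.genes if x not in designated), p.pmid),
        )
        best.terms.append(planted_term)


# ---------------------------------------------------------------------------
# XML / TSV writers
# ---------------------------------------------------------------------------

def _pub_element(pub: _Pub) -> etree._Element:
    art = etree.Element("PubmedArticle")
    cit = etree.SubElement(art, "MedlineCitation", Status="MEDLINE",
                           VersionID=str(pub.version))
    etree.SubElement(cit, "PMID", Version="1").text = str(pub.pmid)
    article = etree.SubElement(cit, "Article")
    journal = etree.SubElement(article, "Journal")
    etree.SubElement(journal, "Title").text = "Synthetic Journal"
    issue = etree.SubElement(journal, "JournalIssue")
    pubdate = etree.SubElement(issue, "PubDate")
    if pub.year is not None:
        etree.SubElement(pubdate, "Year").text = str(pub.year)
    else:
        etree.SubElement(pubdate, "MedlineDate").text = "n.d."
    etree.SubElement(article, "ArticleTitle").text = pub.title
    if pub.authors:
        alist = etree.SubElement(article, "AuthorList")
        for a in pub.authors:
            ae = etree.SubElement(alist, "Author")
            if "collective" in a:
                etree.SubElement(ae, "CollectiveName").text = a["collective"]
                continue
            etree.SubElement(ae, "LastName").text = a["last"]
            etree.SubElement(ae, "ForeName").text = a["fore"]
            etree.SubElement(ae, "Initials").text = a["initials"]
            if a.get("affil"):
                info = etree.SubElement(ae, "AffiliationInfo")
                etree.SubElement(info, "Affiliation").text = a["affil"]
    if pub.terms:
        mlist = etree.SubElement(cit, "MeshHeadingList")
        for ui in pub.terms:
            mh = etree.SubElement(mlist, "MeshHeading")
            dn = etree.SubElement(
                mh, "DescriptorName", UI=ui,
                MajorTopicYN="Y" if ui in pub.major else "N",
            )
            dn.text = f"name-of-{ui}"
    return art


def _write_pubmed_xml(path: Path, pubs: list[_Pub],
                      deleted: Sequence[int] = ()) -> None:
    root = etree.Element("PubmedArticleSet")
    for pub in pubs:
        root.append(_pub_element(pub))
    if deleted:
        dc = etree.SubElement(root, "DeleteCitation")
        for pmid in deleted:
            etree.SubElement(dc, "PMID").text = str(pmid)
    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                       pretty_print=True)
    )


def _write_mesh_xml(path: Path, terms: list[dict],
                    names: Optional[dict[str, str]] = None) -> None:
    root = etree.Element("DescriptorRecordSet")
    for t in terms:
        rec = etree.SubElement(root, "DescriptorRecord")
        etree.SubElement(rec, "DescriptorUI").text = t["ui"]
        dn = etree.SubElement(rec, "DescriptorName")
        etree.SubElement(dn, "String").text = (
            names.get(t["ui"], t["name"]) if names else t["name"]
        )
        if t["trees"]:
            tl = etree.SubElement(rec, "TreeNumberList")
            for tree in t["trees"]:
                etree.SubElement(tl, "TreeNumber").text = tree
    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                       pretty_print=True)
    )


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(
    config: FixtureConfig, out_dir: Union[str, Path]
) -> tuple[BundlePaths, dict]:
    """Write a complete synthetic input bundle and its ground-truth manifest.

    Returns the file paths and the manifest (also written as JSON).  The
    manifest describes the *final* corpus state — after replaying the update
    file's revisions and deletions — keyed by string identifiers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    vocab_terms = _make_vocab(rng, config.n_terms)
    pubs, planted_term, planted_genes, clique = _generate_pubs(
        config, rng, vocab_terms
    )

    n_rev = int(config.revision_fraction * config.n_pubs)
    n_del = int(config.deletion_fraction * config.n_pubs)
    shuffled = list(pubs)
    rng.shuffle(shuffled)
    revised = sorted(p.pmid for p in shuffled[:n_rev])
    deleted = sorted(p.pmid for p in shuffled[n_rev:n_rev + n_del])

    paths = BundlePaths(
        baseline=out / "baseline.xml",
        updates=[out / "update_0001.xml"],
        gene2pubmed=out / "gene2pubmed.tsv",
        mesh=out / "mesh_descriptors.xml",
        pathways=out / "pathways.tsv",
        orthologs=out / "orthologs.tsv",
        interactions=out / "interactions.tsv",
        manifest=out / "manifest.json",
    )
    _write_pubmed_xml(paths.baseline, pubs)

    by_pmid = {p.pmid: p for p in pubs}
    update_pubs = []
    for pmid in revised:
        orig = by_pmid[pmid]
        rev = _Pub(
            pmid=pmid, year=orig.year,
            title=orig.title + " (revised)",
            genes=orig.genes, terms=orig.terms, major=orig.major,
            authors=orig.authors, version=2,
        )
        by_pmid[pmid] = rev
        update_pubs.append(rev)
    _write_pubmed_xml(paths.updates[0], update_pubs, deleted=deleted)

    with open(paths.gene2pubmed, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for pub in pubs:
            for g in pub.genes:
                fh.write(f"{config.taxid}\t{g}\t{pub.pmid}\n")

    _write_mesh_xml(paths.mesh, vocab_terms)

    gene_ids = list(range(1, config.n_genes + 1))
    with open(paths.pathways, "w", encoding="utf-8", newline="\n") as fh:
        for p_i in range(3):
            members = rng.sample(gene_ids, k=min(len(gene_ids), rng.randint(5, 10)))
            for g in sorted(members):
                fh.write(f"PW{p_i + 1}\tGLAD\t{config.taxid}\t{g}\n")

    with open(paths.orthologs, "w", encoding="utf-8", newline="\n") as fh:
        for g in gene_ids:
            if rng.random() < 0.8:
                score = rng.randint(1, 15)
                fh.write(
                    f"{config.taxid}\t{g}\t{config.ortholog_taxid}"
                    f"\t{9000 + g}\t{score}\n"
                )

    with open(paths.interactions, "w", encoding="utf-8", newline="\n") as fh:
        seen_pairs: set[tuple[int, int, str]] = set()
        for _ in range(min(20, config.n_genes * 2)):
            a, b = rng.sample(gene_ids, k=2)
            ev = rng.choice(sorted(corpus_io.EVIDENCE_TYPES))
            key = (min(a, b), max(a, b), ev)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            fh.write(f"{a}\t{b}\t{ev}\n")

    # ground-truth manifest of the FINAL corpus state
    deleted_set = set(deleted)
    final_pubs = {p: r for p, r in by_pmid.items() if p not in deleted_set}
    gene_pubs: dict[int, list[int]] = {}
    term_pubs: dict[str, list[int]] = {}
    pub_entries: dict[str, dict] = {}
    for pmid in sorted(final_pubs):
        pub = final_pubs[pmid]
        for g in pub.genes:
            gene_pubs.setdefault(g, []).append(pmid)
        for ui in pub.terms:
            term_pubs.setdefault(ui, []).append(pmid)
        last_author = None
        for a in reversed(pub.authors):
            if "collective" not in a:
                last_author = [a["last"], a["initials"]]
                break
        pub_entries[str(pmid)] = {
            "year": pub.year,
            "title": pub.title,
            "genes": pub.genes,
            "terms": sorted(pub.terms),
            "major_terms": sorted(pub.major),
            "last_author": last_author,
        }
    manifest = {
        "taxid": config.taxid,
        "seed": config.seed,
        "n_pubs": config.n_pubs,
        "planted_term": planted_term,
        "planted_genes": planted_genes,
        "planted_clique": clique,
        "deleted_pmids": deleted,
        "revised_pmids": revised,
        "gene_pubs": {str(g): sorted(ps) for g, ps in sorted(gene_pubs.items())},
        "term_pubs": {u: sorted(ps) for u, ps in sorted(term_pubs.items())},
        "pubs": pub_entries,
    }
    paths.manifest.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths, manifest


def build_from_bundle(
    paths: BundlePaths, species: Optional[set[int]] = None
) -> tuple[CorpusIndex, MeshVocabulary]:
    """Parse a bundle's files and build the corpus index (convenience)."""
    batches = []
    base = parse_pubmed_xml(str(paths.baseline))
    batches.append((base.records, base.deleted))
    for upd in paths.updates:
        parsed = parse_pubmed_xml(str(upd))
        batches.append((parsed.records, parsed.deleted))
    with open(paths.gene2pubmed, "rb") as fh:
        links = parse_gene2pubmed(fh)
    vocab = parse_mesh_xml(str(paths.mesh))
    taxids = species if species is not None else {l.taxid for l in links}
    return build_index(batches, links, taxids), vocab


# ---------------------------------------------------------------------------
# the fixed toy corpus used in worked examples
# ---------------------------------------------------------------------------

def toy_corpus_T1(out_dir: Union[str, Path]) -> tuple[BundlePaths, dict]:
    """Write the fixed 5-publication, 3-gene, 3-term toy corpus.

    Layout: P1{g1,g2; M1}, P2{g1,g2,g3; M1,M2}, P3{g2; M2}, P4{g3; M3},
    P5{g1; M3}; M2 is a child of M1 (anatomy subtree), M3 sits in the
    disease category.  Authors and years are deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxid = 7227
    terms = [
        {"ui": "D000001", "name": "M1", "trees": ["A01"]},
        {"ui": "D000002", "name": "M2", "trees": ["A01.111"]},
        {"ui": "D000003", "name": "M3", "trees": ["C04"]},
    ]
    A = {"last": "Alpha", "fore": "Alice", "initials": "A",
         "affil": "Alpha Lab, University 1"}
    B = {"last": "Beta", "fore": "Bob", "initials": "B",
         "affil": "Beta Lab, University 2"}
    G = {"last": "Gamma", "fore": "Grace", "initials": "G",
         "affil": "Gamma Lab, University 3"}
    D = {"last": "Delta", "fore": "Dan", "initials": "D",
         "affil": "Delta Lab, University 4"}
    E = {"last": "Epsilon", "fore": "Eve", "initials": "E",
         "affil": "Epsilon Lab, University 5"}
    Z = {"last": "Zeta", "fore": "Zoe", "initials": "Z",
         "affil": "Zeta Lab, University 6"}
    pubs = [
        _Pub(1, 2018, "P1", [1, 2], ["D000001"], set(), [A, B, G]),
        _Pub(2, 2019, "P2", [1, 2, 3], ["D000001", "D000002"], {"D000001"},
             [D, G]),
        _Pub(3, 2020, "P3", [2], ["D000002"], set(), [E]),
        _Pub(4, 2017, "P4", [3], ["D000003"], set(), [Z]),
        _Pub(5, 2021, "P5", [1], ["D000003"], {"D000003"}, [G]),
    ]
    paths = BundlePaths(
        baseline=out / "baseline.xml",
        updates=[],
        gene2pubmed=out / "gene2pubmed.tsv",
        mesh=out / "mesh_descriptors.xml",
        pathways=out / "pathways.tsv",
        orthologs=out / "orthologs.tsv",
        interactions=out / "interactions.tsv",
        manifest=out / "manifest.json",
    )
    _write_pubmed_xml(paths.baseline, pubs)
    names = {t["ui"]: t["name"] for t in terms}
    _write_mesh_xml(paths.mesh, terms, names=names)
    with open(paths.gene2pubmed, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for pub in pubs:
            for g in pub.genes:
                fh.write(f"{taxid}\t{g}\t{pub.pmid}\n")
    paths.pathways.write_text(
        f"Notch\tGLAD\t{taxid}\t1\nNotch\tGLAD\t{taxid}\t2\n",
        encoding="utf-8",
    )
    paths.orthologs.write_text(
        f"{taxid}\t1\t9606\t672\t12\n"
        f"{taxid}\t1\t9606\t673\t3\n"
        f"{taxid}\t2\t9606\t675\t9\n",
        encoding="utf-8",
    )
    paths.interactions.write_text(
        "1\t2\tppi\n1\t2\tgenetic\n2\t3\tinterolog\n", encoding="utf-8"
    )
    manifest = {
        "taxid": taxid,
        "planted_term": None,
        "planted_genes": [],
        "deleted_pmids": [],
        "revised_pmids": [],
        "gene_pubs": {"1": [1, 2, 5], "2": [1, 2, 3], "3": [2, 4]},
        "term_pubs": {
            "D000001": [1, 2], "D000002": [2, 3], "D000003": [4, 5],
        },
        "pubs": {
            str(p.pmid): {
                "year": p.year, "title": p.title, "genes": p.genes,
                "terms": sorted(p.terms), "major_terms": sorted(p.major),
                "last_author": [p.authors[-1]["last"],
                                p.authors[-1]["initials"]],
            }
            for p in pubs
        },
    }
    paths.manifest.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths, manifest
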