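"""Publication-count time series per root-level MeSH term per species.

Research-trend analysis groups a species' gene-associated publications under
the *root-level* terms of one MeSH category (anatomy by default): a
publication counts under a root term for a given year when any of its
headings falls inside that root's descendant closure.  A paper whose
headings sit under two different roots contributes one count to each root
(cross-root multi-counting), but never more than once within a single root.
Publications without a year are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ParameterError
from .index_builder import CorpusIndex
from .mesh_tree import MeshVocabulary, descendants, root_level_terms


@dataclass(frozen=True)
class TrendRow:
    taxid: int
    root_ui: str
    root_name: str
    year: int
    pub_count: int

    CSV_COLUMNS = ("taxid", "root_ui", "root_name", "year", "pub_count")


def category_trends(
    index: CorpusIndex,
    vocab: MeshVocabulary,
    taxid: int,
    category_letter: str = "A",
    year_range: Optional[tuple[int, int]] = None,
    major_topic_only: bool = False,
) -> list[TrendRow]:
    """Yearly publication counts per root term of a MeSH category.

    A publication belongs to the species when linked to >= 1 gene of
    *taxid*.  Rows are emitted only for (root, year) cells with at least one
    publication, sorted by root name, then year.
    """
    if not (len(category_letter) == 1 and category_letter.isalpha()
            and category_letter.isupper()):
        raise ParameterError(
            f"category letter must be a single uppercase letter, "
            f"got {category_letter!r}"
        )
    if year_range is not None and year_range[0] > year_range[1]:
        raise ParameterError(f"empty year range {year_range}")

    roots = sorted(root_level_terms(vocab, category_letter))
    closures = {
        root: {root} | descendants(vocab, root) for root in roots
    }
    species_pubs = {
        pmid for pmid, gs in index.genes_by_pub.items()
        if any(g[0] == taxid for g in gs)
    }
    counts: dict[tuple[str, int], int] = {}
    for pmid in species_pubs:
        rec = index.pub_by_pmid[pmid]
        if rec.year is None:
            continue
        if year_range is not None and not (
            year_range[0] <= rec.year <= year_range[1]
        ):
            continue
        uis = rec.heading_uis(major_topic_only)
        for root, closure in closures.items():
            if uis & closure:
                key = (root, rec.year)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        TrendRow(
            taxid=taxid, root_ui=root, root_name=vocab.name_of(root),
            year=year, pub_count=c,
        )
        for (root, year), c in counts.items()
    ]
    rows.sort(key=lambda r: (r.root_name, r.root_ui, r.year))
    return rows
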