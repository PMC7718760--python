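"""MeSH-term over-representation analysis for a user gene list.

The test is gene-level: a gene is *associated* with a descriptor iff at
least one of its indexed publications carries that descriptor.  With a
background of N literature-covered genes of the species, K of them
associated with a term, and a query list contributing n background genes of
which k are associated, the one-sided upper-tail hypergeometric probability

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n)

scores the term's over-representation, and Benjamini-Hochberg step-up
adjustment over the tested term set controls the FDR.  A publication-level
variant (counting papers rather than genes) is available via ``unit`` but is
non-canonical.

The background is deliberately the set of genes with >= 1 indexed
publication, not all annotated genes: associations are literature-derived,
so literature-covered genes are the correct sampling frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .index_builder import CorpusIndex, Gene, gene_pubs
from .mesh_tree import MeshVocabulary, descendants


@dataclass(frozen=True)
class EnrichmentResult:
    descriptor_ui: str
    descriptor_name: str
    category: str        # sorted category letters, e.g. "CG"
    k: int               # list genes associated with the term
    K: int               # background genes associated with the term
    n: int               # list genes in the background
    N: int               # background size
    fold: float          # (k/n) / (K/N)
    p: float
    q: float

    CSV_COLUMNS = (
        "descriptor_ui", "descriptor_name", "category",
        "k", "K", "n", "N", "fold", "p", "q",
    )


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed stably in log space.

    Bounds are validated and the violated inequality is named.
    """
    if not 0 <= K <= N:
        raise ParameterError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ParameterError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ParameterError(
            f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the pmf via log-gamma
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _gene_term_associations(
    index: CorpusIndex,
    genes: Sequence[Gene],
    major_topic_only: bool,
) -> dict[Gene, set[str]]:
    assoc: dict[Gene, set[str]] = {}
    for g in genes:
        uis: set[str] = set()
        for pmid in gene_pubs(index, *g):
            uis |= index.pub_by_pmid[pmid].heading_uis(major_topic_only)
        assoc[g] = uis
    return assoc


def mesh_enrichment(
    index: CorpusIndex,
    vocab: MeshVocabulary,
    gene_list: Sequence[int],
    taxid: int,
    category_filter: Optional[str] = None,
    min_k: int = 2,
    unit: str = "gene",
    aggregate_descendants: bool = False,
    major_topic_only: bool = False,
) -> list[EnrichmentResult]:
    """Over-represented MeSH terms in the literature of a gene list.

    ``min_k`` (default 2) suppresses singleton noise; ``category_filter``
    restricts the tested set *before* testing, so it also shrinks the BH
    family.  ``aggregate_descendants`` pools each descriptor with its whole
    subtree before counting.  Results sort ascending by p, ties by name.
    """
    if not gene_list:
        raise ParameterError("gene list is empty")
    if unit not in ("gene", "publication"):
        raise ParameterError(f"unit must be 'gene' or 'publication', got {unit!r}")
    background = sorted(index.genes_of_taxid(taxid))
    if not background:
        raise ParameterError(f"no indexed genes for taxid {taxid}")

    if unit == "gene":
        list_genes = [
            (taxid, g) for g in dict.fromkeys(gene_list)
            if (taxid, g) in index.pubs_by_gene
        ]
        if not list_genes:
            raise ParameterError("no list gene has publications in the index")
        assoc = _gene_term_associations(index, background, major_topic_only)
        N = len(background)
        n = len(list_genes)
        term_K: dict[str, int] = {}
        term_k: dict[str, int] = {}
        list_set = set(list_genes)
        for g, uis in assoc.items():
            for ui in uis:
                term_K[ui] = term_K.get(ui, 0) + 1
                if g in list_set:
                    term_k[ui] = term_k.get(ui, 0) + 1
    else:
        # publication-level variant: units are papers, not genes
        bg_pubs: set[int] = set()
        for g in background:
            bg_pubs |= index.pubs_by_gene[g]
        list_pubs: set[int] = set()
        for gid in gene_list:
            list_pubs |= gene_pubs(index, taxid, gid)
        if not list_pubs:
            raise ParameterError("no list gene has publications in the index")
        N = len(bg_pubs)
        n = len(list_pubs)
        term_K, term_k = {}, {}
        for pmid in bg_pubs:
            for ui in index.pub_by_pmid[pmid].heading_uis(major_topic_only):
                term_K[ui] = term_K.get(ui, 0) + 1
                if pmid in list_pubs:
                    term_k[ui] = term_k.get(ui, 0) + 1

    if aggregate_descendants:
        term_K, term_k = _aggregate_subtrees(
            index, vocab, term_K.keys(), taxid, gene_list, unit,
            major_topic_only, N,
        )

    # The BH family is defined list-independently: descriptors with enough
    # background support (K >= min_k) in the requested category.  Filtering
    # the family by the list's own overlap k would condition the tested set
    # on the query and inflate false discoveries under the null; k >= min_k
    # governs only which rows are reported.
    tested: list[tuple[str, str, str, int, int]] = []
    for ui, K in sorted(term_K.items()):
        k = term_k.get(ui, 0)
        if K < min_k:
            continue
        if ui in vocab:
            d = vocab.get(ui)
            name = d.name
            category = "".join(sorted(d.category))
        else:
            name, category = ui, ""
        if category_filter is not None and category_filter not in category:
            continue
        tested.append((ui, name, category, k, K))
    if not tested:
        return []

    pvals = [hypergeom_upper_tail(k, K, n, N) for _ui, _nm, _c, k, K in tested]
    qvals = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            descriptor_ui=ui, descriptor_name=name, category=category,
            k=k, K=K, n=n, N=N,
            fold=(k / n) / (K / N),
            p=p, q=q,
        )
        for (ui, name, category, k, K), p, q in zip(tested, pvals, qvals)
        if k >= min_k
    ]
    results.sort(key=lambda r: (r.p, r.descriptor_name, r.descriptor_ui))
    return results


def _aggregate_subtrees(index, vocab, uis, taxid, gene_list, unit,
                        major_topic_only, N):
    """Recount each tested descriptor pooled with its descendant closure."""
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    background = sorted(index.genes_of_taxid(taxid))
    list_set = {(taxid, g) for g in gene_list}
    assoc = _gene_term_associations(index, background, major_topic_only)
    for ui in uis:
        closure = {ui}
        if ui in vocab:
            closure |= descendants(vocab, ui)
        if unit == "gene":
            K = sum(1 for g in background if assoc[g] & closure)
            k = sum(
                1 for g in background if g in list_set and assoc[g] & closure
            )
        else:
            pubs = set()
            for u in closure:
                pubs |= index.pubs_by_mesh.get(u, set())
            bg_pubs = set(index.pub_by_pmid) & pubs
            list_pubs = set()
            for g in list_set:
                list_pubs |= index.pubs_by_gene.get(g, set())
            K = len(bg_pubs)
            k = len(bg_pubs & list_pubs)
        term_K[ui], term_k[ui] = K, k
    return term_K, term_k
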