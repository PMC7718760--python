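"""Independent brute-force oracles used across the test suite.

Everything here recomputes expected results from first principles — raw
manifest dictionaries, pairwise string checks, exact rational arithmetic —
without going through the package's indexes or query paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


# ---------------------------------------------------------------------------
# MeSH hierarchy (O(n^2) pairwise prefix checks over (ui, tree_numbers))
# ---------------------------------------------------------------------------

def brute_descendants(terms: dict[str, set[str]], ui: str) -> set[str]:
    out = set()
    for other, other_trees in terms.items():
        if other == ui:
            continue
        for t in terms[ui]:
            for ot in other_trees:
                if ot.startswith(t + "."):
                    out.add(other)
    return out


def brute_children(terms: dict[str, set[str]], ui: str) -> set[str]:
    out = set()
    for other, other_trees in terms.items():
        if other == ui:
            continue
        for t in terms[ui]:
            for ot in other_trees:
                if ot.startswith(t + ".") and "." not in ot[len(t) + 1:]:
                    out.add(other)
    return out


def brute_roots(terms: dict[str, set[str]], letter: str) -> set[str]:
    return {
        ui for ui, trees in terms.items()
        if any("." not in t and t[0] == letter for t in trees)
    }


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail (rational arithmetic)
# ---------------------------------------------------------------------------

def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    total = comb(N, n)
    s = sum(comb(K, i) * comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)
            if n - i <= N - K)
    return Fraction(s, total)


def enumerate_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(|draw ∩ marked| >= k) by enumerating all C(N, n) draws."""
    marked = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(range(N), n)
        if len(marked.intersection(draw)) >= k
    )
    return Fraction(hits, comb(N, n))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up by hand
# ---------------------------------------------------------------------------

def step_up_bh(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------
# manifest recounts (queries recomputed from the ground-truth dicts)
# ---------------------------------------------------------------------------

def manifest_gene_pubs(manifest: dict, gene_id: int) -> set[int]:
    return set(manifest["gene_pubs"].get(str(gene_id), ()))


def manifest_gene_to_mesh(manifest: dict, gene_id: int,
                          major_only: bool = False) -> dict[str, int]:
    counts: dict[str, int] = {}
    for pmid in manifest_gene_pubs(manifest, gene_id):
        entry = manifest["pubs"][str(pmid)]
        terms = entry["major_terms"] if major_only else entry["terms"]
        for ui in terms:
            counts[ui] = counts.get(ui, 0) + 1
    return counts


def manifest_mesh_to_gene(manifest: dict, uis: set[str]) -> dict[int, int]:
    pmids = {
        int(pmid) for pmid, entry in manifest["pubs"].items()
        if set(entry["terms"]) & uis
    }
    counts: dict[int, int] = {}
    for pmid in pmids:
        for g in manifest["pubs"][str(pmid)]["genes"]:
            counts[g] = counts.get(g, 0) + 1
    return counts


def manifest_co_cited(manifest: dict, gene_id: int) -> dict[int, int]:
    weights: dict[int, int] = {}
    for pmid in manifest_gene_pubs(manifest, gene_id):
        for g in manifest["pubs"][str(pmid)]["genes"]:
            if g != gene_id:
                weights[g] = weights.get(g, 0) + 1
    return weights


def manifest_people(manifest: dict, gene_id: int) -> dict[tuple, dict]:
    """person (last, initials) -> {'pubs': set, 'latest': (year, pmid)}."""
    out: dict[tuple, dict] = {}
    for pmid in manifest_gene_pubs(manifest, gene_id):
        entry = manifest["pubs"][str(pmid)]
        if entry["last_author"] is None:
            continue
        key = tuple(entry["last_author"])
        g = out.setdefault(key, {"pubs": set(), "latest": None})
        g["pubs"].add(pmid)
        rank = (entry["year"] if entry["year"] is not None else -1, pmid)
        if g["latest"] is None or rank > g["latest"]:
            g["latest"] = rank
    return out


def manifest_trends(manifest: dict, closure_uis: set[str]) -> dict[int, int]:
    """year -> publication count for one root-term closure."""
    counts: dict[int, int] = {}
    for _pmid, entry in manifest["pubs"].items():
        if entry["year"] is None:
            continue
        if set(entry["terms"]) & closure_uis:
            counts[entry["year"]] = counts.get(entry["year"], 0) + 1
    return counts
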