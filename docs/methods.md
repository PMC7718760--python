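# Methods

This note documents the models, conventions and design choices behind
`litmine`: what each component assumes, which knobs matter, what the
synthetic corpora do and do not emulate, and the numerical details that
make outputs reproducible byte for byte.

## Corpus model

A publication record carries a PMID, an optional year, title and journal,
an ordered MeSH heading list (descriptor UI, preferred name, major-topic
flag) and an ordered author list. Only descriptor-level headings are read;
qualifier subheadings and chemical/substance annotations are ignored — all
queries operate at descriptor granularity. The year comes from
`PubDate/Year` when present, otherwise from the first four-digit token of
`MedlineDate` (so "1998 Dec-1999 Jan" → 1998); records without a
recoverable year are retained for association queries but excluded from
trend series.

Parsing is streaming (`lxml.iterparse` with element cleanup), so memory is
constant in the number of citations; full-scale MEDLINE baselines are
hundreds of gigabytes and must not be materialized. Malformed *optional*
fields degrade to absent; only structural failures (non-XML input,
duplicate MeSH UIs, invalid interaction evidence) abort a file. A parse
report counts parsed and skipped elements so that `parsed + skipped`
always equals the number of citation elements seen.

### Revision and deletion semantics

MEDLINE distributes a yearly baseline plus incremental updates; an update
may re-issue a PMID (revision, possibly with a higher `VersionID`) or list
it under `DeleteCitation`. Batches are replayed oldest-first: the record
from the latest batch wins, ties broken by higher version; a deleted PMID
disappears from every map unless a later batch re-issues it. Building from
(baseline + updates) is equivalent to building from the merged final
record set — a property checked on every generated bundle.

### Gene filter and admitted species

After merging, only publications linked by gene2pubmed to at least one
gene of an admitted species are kept; this is what turns the raw
literature into a gene-centric corpus. The admitted list is configuration,
not a constant: the shipped default is human plus nine major model
organisms (taxids 9606, 10090, 10116, 7955, 8364, 7227, 6239, 559292,
4896, 3702), chosen as the conventional model-organism panel; any taxid
set can be passed. Links to deleted PMIDs are dropped (counted), links to
PMIDs never seen in any batch are counted as dangling, neither is fatal.

The index persists to a single-file SQLite store (publications, headings,
authors, affiliations, gene links, and optionally the MeSH vocabulary), so
query commands run without re-parsing sources. A server database would be
a deployment concern; an embedded store keeps the artifact self-contained.

## MeSH hierarchy

Hierarchy is defined purely by tree-number strings: X is a descendant of Y
iff some tree number of X extends a tree number of Y at a dot boundary
(`A01.111` is under `A01`; `A011` is not). Children are exactly one dotted
level below; root-level terms are undotted tree numbers; a descriptor's
category is the set of leading letters of its tree numbers, and a
descriptor under several categories contributes to each category's
filtered views. Descendant closure is computed by a sorted prefix scan
over the tree-number index, which equals the O(n²) pairwise check (a
property test). Name lookup is case-insensitive exact match on preferred
names; entry-term synonyms and supplementary concept records are out of
scope.

## Queries

All result lists have total, documented sort orders (primary count
descending, ties by name/label, further ties by identifier), so CSV
exports are byte-stable across runs.

* **gene → MeSH** counts, per descriptor, the publications of the gene
  carrying it; with ortholog inclusion each row is tagged with its
  contributing `source_gene` so species remain separable. A category
  letter filters descriptors by tree-number category; `--major-topic-only`
  restricts to headings flagged as central topics (the default counts all
  headings, since the convention used by the original index is unstated).
* **MeSH → gene** unions the term's publications (optionally with its
  whole descendant subtree) and counts genes of the requested species.
* **co-citation** weights a partner gene by the number of shared
  publications; weights are symmetric. Partners default to the input
  gene's species (a flag lifts this), since cross-species co-citation
  mixes identifier spaces.
* **people** groups a scope's publications by *last person author* —
  the final author-list entry that is a person, skipping trailing
  consortium entries; publications with no person author contribute
  nothing. Person identity is the diacritic-folded, lowercased
  `lastname|initials` pair (plus a small table for stroked letters such as
  ł/ø that NFKD leaves intact); homonyms collapse, which is a known
  limitation without ORCID-style identifiers. Recency is (year, then
  larger PMID) so records without years sort oldest deterministically;
  the reported address is the author's first affiliation string on their
  most recent paper. Pathway-level search merges per-gene results by
  person, counting distinct publications once and reporting the pathway
  genes each person has published on.
* **ortholog mapping** applies score-table pairs in both stored
  directions, supports one-to-many mappings, and filters by a minimum
  integrative score.

## Enrichment

The test is gene-level: a gene is associated with a descriptor iff ≥ 1 of
its indexed publications carries it. The background is the set of genes of
the species with ≥ 1 indexed publication — not all annotated genes —
because the associations are literature-derived, so literature-covered
genes are the correct sampling frame. With `N` background genes, `K`
associated with the term, `n` list genes in the background and `k` of them
associated, the p-value is the upper hypergeometric tail
P(X ≥ k), evaluated via `scipy.stats.hypergeom.sf` (log-gamma based, stable
for large counts); `q` is Benjamini–Hochberg step-up via
`statsmodels.stats.multitest`.

Two family-definition details matter:

* **The BH family is list-independent.** Terms enter the tested family
  when their *background* support satisfies `K ≥ min_k` (after any
  category filter). Conditioning the family on the list's own overlap
  `k` would select terms for being overrepresented in the query and
  measurably inflates null false discoveries (in calibration runs the
  fraction of null lists with min q > 0.05 fell below its nominal level);
  with the list-independent family, null calibration is clean. The
  `min_k` threshold on `k` (default 2) only suppresses singleton rows
  from the report.
* **Category filtering precedes testing**, so restricting to, say,
  "phenomena and processes" also shrinks the BH family.

A publication-level variant (counting papers instead of genes) is
available behind `unit="publication"` but is non-canonical; descriptor
counts are not hierarchy-expanded by default, with subtree aggregation
behind a flag.

## Trends

For one MeSH category (anatomy by default), each root-level term defines a
closure (itself plus all descendants). A publication of the species counts
once under a root for its year when any heading falls in the closure;
headings under two different roots count once for each root, and multiple
headings under one root still count once. Species attribution is linkage
to ≥ 1 gene of the taxid, so one publication may serve several species'
series.

## Networks and word clouds

The co-citation graph is a star around the query gene over partners with
weight ≥ `min_weight` (default 1; no display threshold convention exists,
so it is configurable). Interaction evidence (ppi / genetic / interolog)
only annotates edges already present — the overlay never adds nodes or
edges, keeping topology purely literature-derived, and is idempotent.
Word-cloud weights map counts linearly onto [w_min, w_max] = [10, 60] by
default (all-equal counts, including a single term, map to w_max); a log
option exists for long-tailed count distributions. Exports (GraphML via
networkx, Cytoscape-JSON elements dialect, SIF) order nodes by label and
edges by endpoint pair, so repeated exports are byte-identical.

## Synthetic corpora

The generator emits real on-disk files in the standard formats — baseline
XML, one update file with revisions and a `DeleteCitation` block,
gene2pubmed TSV, MeSH descriptor XML with guaranteed depth-3 chains in two
categories, pathway/ortholog/interaction tables — plus a JSON manifest
that exactly describes the final corpus state, so every query can be
recounted independently of the index. All randomness flows through one
seeded `random.Random`; identical config + seed gives byte-identical
bundles.

Default shape (chosen once as a desk-scale but structurally realistic
corpus): 200 publications, 100 genes of one species, 50 descriptors, 30
authors, years 2000–2020, 5% of records without a year, 1–3 genes and 0–4
terms per publication, term choice skewed by a rank power-law (exponent
1.2), 30% of headings major-topic.

**Planted enrichment** designates per-gene associations — each list gene
becomes term-associated with probability 0.8, each background gene with
0.1 — and realizes them by attaching the term to publications whose gene
sets lie inside the designated set, with one forced minimal-spill
attachment for designated genes otherwise uncovered. The probabilities are
per gene because the enrichment test counts genes; attaching the term per
publication instead lets co-published background genes absorb it until
half the background is associated and the gene-level signal washes out.
**Planted co-citation** makes a designated clique co-publish at a given
rate.

What the generator does *not* emulate: real title/abstract text (nothing
is text-mined), entry-term synonymy, realistic author-name ambiguity,
journal structure, or the scale of a full baseline. Passing tests
therefore demonstrate correctness of the indexing and query semantics, not
robustness to the noise profile of real MEDLINE exports.

## Problem sizes in tests and the acceptance script

Correctness is checked on corpora of 80–400 publications (20 seeded
bundles for oracle equivalence), the exhaustive hypergeometric grid runs
to N ≤ 12 in tests and N ≤ 10 in the script, BH is verified on 1,000
random vectors, planted recovery uses the 200-publication default
(10 replicates in the script), and null calibration uses 100 replicate
corpora. These sizes make every count exhaustively recountable by brute
force while keeping the whole suite in seconds.

## Known limitations

* Person identity by (last name, initials) collapses homonyms and splits
  authors who change names or initials.
* Preferred-name matching only; users of real MeSH files must supply
  descriptor UIs or exact names.
* The enrichment background requires the gene list's species to be
  indexed; cross-species lists must be ortholog-mapped first.
* Incremental updates rebuild the index from batches; there is no
  in-place mutation of an existing store.
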