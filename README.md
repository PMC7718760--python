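# litmine

Offline, gene-centric mining of MEDLINE-style literature.

Searching the biomedical literature by gene *name* is unreliable: synonyms
miss papers and ambiguous symbols retrieve irrelevant ones. `litmine`
sidesteps free text entirely and mines two expert-curated annotation layers
that already exist for every PubMed record: the **MeSH** (Medical Subject
Headings) index attached to each citation and the NCBI **gene2pubmed**
links between genes and publications. From local copies of these release
files the package builds an embedded index of a gene-associated literature
corpus and answers the questions a bench scientist or clinician actually
asks:

* **gene → MeSH** — what subjects is this gene's literature about
  (with word-cloud weights, optionally pooled with its orthologs)?
* **MeSH → gene** — which genes does the literature on a subject involve
  (optionally expanding the term to its more specific descendants)?
* **co-citation** — which genes share publications with this one, as a
  network annotated with known protein–protein, genetic and interolog
  interactions?
* **batch** — how many publications back each gene on a list?
* **people** — who are the last authors (a proxy for supervising
  investigators) of the literature on a gene or pathway, with their latest
  year and address?
* **enrichment** — which MeSH terms are over-represented in the literature
  of a gene list?
* **trends** — how do publication counts under root-level MeSH categories
  (e.g. anatomy) evolve over time per species?
* **ortholog mapping** — translate a gene list between species using
  DIOPT-style ortholog score tables.

It is a library plus a thin CLI; rendering (word clouds, network drawings)
is out of scope — machine-readable CSV/GraphML/Cytoscape-JSON/SIF files are
the output.

## The statistics at the core

**Enrichment.** For a query list contributing $n$ genes out of a background
of $N$ literature-covered genes of the species, a term associated with $K$
background genes and $k$ list genes is scored by the one-sided upper-tail
hypergeometric probability

$$p \;=\; \sum_{i=k}^{\min(K,n)} \frac{\binom{K}{i}\binom{N-K}{n-i}}{\binom{N}{n}},$$

with fold enrichment $(k/n)/(K/N)$ and Benjamini–Hochberg step-up
adjustment $q$ across the tested family of terms. A gene is *associated*
with a term when at least one of its indexed publications carries the
term's descriptor. The BH family is defined list-independently (all terms
with background support $K \ge$ `min_k` in the requested category); the
`min_k` threshold on $k$ only filters which rows are reported.

**Hierarchy.** MeSH descriptors carry dotted *tree numbers* (`C04.588`);
descendant relations are exactly dot-boundary prefix extensions, so
"include child terms", root-level grouping for trends, and category filters
(A = anatomy, C = diseases, G = phenomena and processes, …) are pure string
operations on tree numbers.

**Corpus semantics.** MEDLINE ships as a baseline plus incremental updates
that may revise (same PMID, higher `VersionID`) or delete (`DeleteCitation`)
earlier records. The index replays batches oldest-first with
last-version-wins semantics, then keeps only publications linked to ≥ 1
gene of an admitted species (default: human and nine major model
organisms).

## Worked example

Everything is testable offline: the `synthetic_fixtures` module writes a
complete input bundle (PubMed-style XML, gene2pubmed TSV, MeSH XML,
pathway/ortholog/interaction tables) plus a ground-truth manifest. The
fixed toy corpus has 5 publications, 3 fly genes and 3 MeSH terms:

```bash
litmine fixtures --toy --out-dir bundle
litmine build --pubmed bundle/baseline.xml \
              --gene2pubmed bundle/gene2pubmed.tsv \
              --mesh bundle/mesh_descriptors.xml \
              --out corpus.sqlite
litmine gene2mesh --index corpus.sqlite --gene 7227:1 --out g2m.csv
cat g2m.csv
```

prints (CSV, CRLF line ends):

```
descriptor_ui,descriptor_name,pub_count,pmids,source_gene
D000001,M1,2,1;2,7227:1
D000002,M2,1,2,7227:1
D000003,M3,1,5,7227:1
```

Gene 1 appears in publications 1, 2 and 5; term `M1` annotates
publications 1 and 2 (hence `pub_count` 2), and terms `M2`/`M3` one each —
rows are ranked by publication count with name tie-breaks. Likewise

```bash
litmine mesh2gene --index corpus.sqlite --term M1 --include-children \
                  --species 7227 --out m2g.csv
```

expands `M1` to its child `M2` (tree numbers `A01` → `A01.111`), collects
publications {1, 2, 3} and ranks genes 2, 1, 3 with counts 3, 2, 1. The
same index drives `cocite`, `people`, `enrich`, `trends`, `network` and
`wordcloud`; run `litmine --help` for all subcommands.

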