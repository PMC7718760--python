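"""Co-citation network with interaction-evidence overlay, and word-cloud weights.

The co-citation graph is a star around the query gene: one node per co-cited
partner above the weight threshold, edge weight = number of shared
publications.  Known molecular interactions (protein-protein, genetic,
interolog) *annotate* matching edges — the overlay never adds nodes or
edges, so the graph topology is purely literature-derived.

Word-cloud weights map per-term publication counts linearly onto a display
size range, the convention used when scaling term size by publication count.
Exports are deterministic (nodes ordered by label, edges by endpoint pair)
in GraphML, Cytoscape JSON (elements dialect) and SIF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import networkx as nx

from .corpus_io import InteractionEdge
from .errors import ParameterError
from .index_builder import CorpusIndex, Gene
from .query import CoCitationRow, GeneMeshRow, co_cited, gene_label


@dataclass(frozen=True)
class GraphNode:
    gene: Gene
    label: str
    is_query: bool


@dataclass(frozen=True)
class GraphEdge:
    gene_a: Gene
    gene_b: Gene
    weight: int
    evidence: frozenset[str]
    pmids: frozenset[int]


@dataclass
class CoCitationGraph:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.label,
                taxid=node.gene[0], gene_id=node.gene[1],
                is_query=node.is_query,
            )
        for e in self.edges:
            g.add_edge(
                gene_label(e.gene_a), gene_label(e.gene_b),
                weight=e.weight,
                evidence=";".join(sorted(e.evidence)),
                pmids=";".join(str(p) for p in sorted(e.pmids)),
            )
        return g


def build_cocitation_graph(
    index: CorpusIndex,
    gene: Gene,
    min_weight: int = 1,
    interactions: Iterable[InteractionEdge] = (),
    same_species_only: bool = True,
    symbols: Optional[dict[Gene, str]] = None,
) -> CoCitationGraph:
    """Star graph of genes co-cited with *gene*, evidence-annotated.

    Partners below *min_weight* are dropped (nodes and edges).  Interaction
    evidence matches pairs order-insensitively by gene id and only decorates
    edges already present.
    """
    rows: list[CoCitationRow] = co_cited(
        index, gene, same_species_only=same_species_only, symbols=symbols
    )
    rows = [r for r in rows if r.weight >= min_weight]
    evidence_by_pair: dict[frozenset[int], set[str]] = {}
    for edge in interactions:
        pair = frozenset((edge.gene_a, edge.gene_b))
        evidence_by_pair.setdefault(pair, set()).add(edge.evidence)

    nodes = [GraphNode(gene=gene, label=gene_label(gene, symbols), is_query=True)]
    edges = []
    for r in rows:
        partner = (r.taxid, r.gene_id)
        nodes.append(GraphNode(gene=partner, label=r.label, is_query=False))
        pair = frozenset((gene[1], r.gene_id))
        edges.append(
            GraphEdge(
                gene_a=gene, gene_b=partner,
                weight=r.weight,
                evidence=frozenset(evidence_by_pair.get(pair, ())),
                pmids=r.pmids,
            )
        )
    nodes.sort(key=lambda n: (not n.is_query, n.label))
    edges.sort(key=lambda e: (gene_label(e.gene_a), gene_label(e.gene_b)))
    return CoCitationGraph(nodes=nodes, edges=edges)


@dataclass(frozen=True)
class WordCloudRow:
    descriptor_name: str
    pub_count: int
    display_weight: float

    CSV_COLUMNS = ("descriptor_name", "pub_count", "display_weight")


def wordcloud_weights(
    rows: Sequence[GeneMeshRow],
    w_min: float = 10.0,
    w_max: float = 60.0,
    log_scale: bool = False,
) -> list[WordCloudRow]:
    """Map per-term publication counts onto display sizes in [w_min, w_max].

    Linear by default (``log_scale`` compresses long-tailed counts).  When
    all counts are equal — including a single row — every term gets w_max.
    """
    if not rows:
        raise ParameterError("word-cloud rows are empty")
    if w_min > w_max:
        raise ParameterError(f"w_min {w_min} exceeds w_max {w_max}")
    import math

    counts = [r.pub_count for r in rows]
    xform = (lambda c: math.log(c)) if log_scale else (lambda c: float(c))
    lo, hi = xform(min(counts)), xform(max(counts))
    out = []
    for r in rows:
        if hi == lo:
            w = w_max
        else:
            w = w_min + (xform(r.pub_count) - lo) * (w_max - w_min) / (hi - lo)
        out.append(
            WordCloudRow(
                descriptor_name=r.descriptor_name,
                pub_count=r.pub_count,
                display_weight=w,
            )
        )
    return out


GRAPH_FORMATS = ("graphml", "cyjs", "sif")


def export_graph(
    graph: CoCitationGraph,
    destination: Union[str, IO],
    format: str = "graphml",
) -> None:
    """Write the graph as GraphML, Cytoscape JSON (elements) or SIF.

    Element order is deterministic, so repeated exports are byte-identical.
    """
    if format not in GRAPH_FORMATS:
        raise ParameterError(
            f"unknown graph format {format!r}; choose from {GRAPH_FORMATS}"
        )
    if format == "graphml":
        nx.write_graphml(graph.to_networkx(), destination, encoding="utf-8")
        return

    if format == "sif":
        lines = [
            f"{gene_label(e.gene_a)}\tco_cited\t{gene_label(e.gene_b)}"
            for e in graph.edges
        ]
        text = "\n".join(lines) + ("\n" if lines else "")
    else:  # cyjs
        payload = {
            "elements": {
                "nodes": [
                    {
                        "data": {
                            "id": n.label,
                            "taxid": n.gene[0],
                            "gene_id": n.gene[1],
                            "is_query": n.is_query,
                        }
                    }
                    for n in graph.nodes
                ],
                "edges": [
                    {
                        "data": {
                            "source": gene_label(e.gene_a),
                            "target": gene_label(e.gene_b),
                            "weight": e.weight,
                            "evidence": sorted(e.evidence),
                            "pmids": sorted(e.pmids),
                        }
                    }
                    for e in graph.edges
                ],
            }
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    else:
        destination.write(text)
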