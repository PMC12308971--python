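"""Ranked queries, multi-marker annotation, and co-occurrence graph export.

A :class:`Deployment` wraps the filtered, aggregated relation table with
both concept catalogs and answers the questions the atlas exists for:
which cell types co-occur with this gene (and vice versa), which cell type
does this list of marker genes point at, and what does the co-occurrence
neighbourhood of a set of query terms look like as a graph.

Rankings are total and deterministic: score descending, then ``c_pmid``
descending, then counterpart canonical name ascending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import pandas as pd

from .atlas_store import AggregatedRelation
from .concept_mapping import ConceptCatalog, ConceptRecord, resolve_query_term
from .corpus_io import EntityClass
from .scoring import relevance_score


@dataclass(frozen=True)
class QueryHit:
    """One ranked counterpart concept for a query, with its evidence."""

    concept: ConceptRecord
    c_pmid: int
    c_total: int
    score: float
    pmids: tuple[int, ...] = ()


@dataclass
class QueryParams:
    exact: bool = True
    gene_type_filter: str | None = None
    score_cutoff: float = 0.0
    limit: int | None = None


class Deployment:
    """Queryable deployment table bound to its gene and cell catalogs."""

    def __init__(
        self,
        rows: Sequence[AggregatedRelation],
        gene_catalog: ConceptCatalog,
        cell_catalog: ConceptCatalog,
    ) -> None:
        self.rows = list(rows)
        self.gene_catalog = gene_catalog
        self.cell_catalog = cell_catalog
        self._by_gene: dict[str, list[AggregatedRelation]] = {}
        self._by_cell: dict[str, list[AggregatedRelation]] = {}
        for row in self.rows:
            self._by_gene.setdefault(row.gene_cui, []).append(row)
            self._by_cell.setdefault(row.cell_cui, []).append(row)

    def relations_of_gene(self, gene_cui: str) -> list[AggregatedRelation]:
        return list(self._by_gene.get(gene_cui, []))

    def relations_of_cell(self, cell_cui: str) -> list[AggregatedRelation]:
        return list(self._by_cell.get(cell_cui, []))


def _rank(hits: list[QueryHit], params: QueryParams) -> list[QueryHit]:
    hits = [h for h in hits if h.score >= params.score_cutoff]
    hits.sort(key=lambda h: (-h.score, -h.c_pmid, h.concept.canonical_name))
    if params.limit is not None:
        hits = hits[: params.limit]
    return hits


def query_gene(
    deployment: Deployment, term: str, params: QueryParams | None = None
) -> list[QueryHit]:
    """Rank the cell-type counterparts of a gene query term.

    The term is resolved through the gene catalog (exact or substring
    matching per ``params.exact``); counterpart hits of all resolved genes
    are scored with the relevance score, cut at ``score_cutoff``, ranked,
    and truncated to ``limit``. An unresolvable term yields an empty list.
    """
    params = params or QueryParams()
    concepts = resolve_query_term(term, deployment.gene_catalog, exact=params.exact)
    if params.gene_type_filter is not None:
        concepts = [c for c in concepts if c.gene_type == params.gene_type_filter]
    hits = []
    for concept in concepts:
        for row in deployment.relations_of_gene(concept.cui):
            counterpart = deployment.cell_catalog.records.get(row.cell_cui)
            if counterpart is None:
                continue
            hits.append(
                QueryHit(
                    concept=counterpart,
                    c_pmid=row.c_pmid,
                    c_total=row.c_total,
                    score=relevance_score(row.c_pmid, row.c_total),
                    pmids=row.pmids,
                )
            )
    return _rank(hits, params)


def query_cell(
    deployment: Deployment, term: str, params: QueryParams | None = None
) -> list[QueryHit]:
    """Rank the gene counterparts of a cell-type query term.

    Mirror of :func:`query_gene`; ``gene_type_filter`` here restricts the
    returned counterpart genes (e.g. protein-coding only).
    """
    params = params or QueryParams()
    concepts = resolve_query_term(term, deployment.cell_catalog, exact=params.exact)
    hits = []
    for concept in concepts:
        for row in deployment.relations_of_cell(concept.cui):
            counterpart = deployment.gene_catalog.records.get(row.gene_cui)
            if counterpart is None:
                continue
            if (
                params.gene_type_filter is not None
                and counterpart.gene_type != params.gene_type_filter
            ):
                continue
            hits.append(
                QueryHit(
                    concept=counterpart,
                    c_pmid=row.c_pmid,
                    c_total=row.c_total,
                    score=relevance_score(row.c_pmid, row.c_total),
                    pmids=row.pmids,
                )
            )
    return _rank(hits, params)


CombinationRule = Literal["sum", "mean", "count"]


@dataclass
class MarkerAnnotation:
    """One candidate cell type for a marker-gene list."""

    concept: ConceptRecord
    combined_score: float
    contributions: dict[str, float] = field(default_factory=dict)
    c_pmid_max: int = 0


@dataclass
class MarkerAnnotationResult:
    ranking: list[MarkerAnnotation]
    resolution_notes: dict[str, str] = field(default_factory=dict)


def annotate_marker_list(
    deployment: Deployment,
    genes: Sequence[str],
    params: QueryParams | None = None,
    combination: CombinationRule = "sum",
) -> MarkerAnnotationResult:
    """Rank cell types for a list of marker genes.

    Each gene contributes its relevance score to every cell type it hits;
    per cell type the contributions are combined by ``sum`` (default: rewards
    both marker breadth and strength), ``mean`` over matched genes, or
    ``count`` of matched genes. Genes that do not resolve, or resolve but hit
    nothing, are reported in the resolution notes. A single-gene list
    reduces to :func:`query_gene`'s ranking.
    """
    if not genes:
        raise ValueError("marker gene list must be non-empty")
    params = params or QueryParams()
    per_cell: dict[str, MarkerAnnotation] = {}
    notes: dict[str, str] = {}
    for gene in genes:
        hits = query_gene(deployment, gene, params)
        if not hits:
            resolved = resolve_query_term(gene, deployment.gene_catalog, exact=params.exact)
            notes[gene] = "unresolved term" if not resolved else "no relations above cutoff"
            continue
        for hit in hits:
            entry = per_cell.get(hit.concept.cui)
            if entry is None:
                entry = MarkerAnnotation(concept=hit.concept, combined_score=0.0)
                per_cell[hit.concept.cui] = entry
            # one contribution per (gene, cell): keep the best-scoring resolution
            entry.contributions[gene] = max(entry.contributions.get(gene, 0.0), hit.score)
            entry.c_pmid_max = max(entry.c_pmid_max, hit.c_pmid)
    for entry in per_cell.values():
        if combination == "sum":
            entry.combined_score = sum(entry.contributions.values())
        elif combination == "mean":
            entry.combined_score = sum(entry.contributions.values()) / len(entry.contributions)
        elif combination == "count":
            entry.combined_score = float(len(entry.contributions))
        else:
            raise ValueError(f"unknown combination rule: {combination!r}")
    ranking = sorted(
        per_cell.values(),
        key=lambda e: (-e.combined_score, -e.c_pmid_max, e.concept.canonical_name),
    )
    return MarkerAnnotationResult(ranking=ranking, resolution_notes=notes)


NodeWeightRule = Literal["max", "sum"]


def build_cooccurrence_graph(
    deployment: Deployment,
    terms: Sequence[str],
    params: QueryParams | None = None,
    node_weight: NodeWeightRule = "max",
) -> nx.Graph:
    """Merge the ranked results of several query terms into one graph.

    Each term is resolved against both catalogs; every resulting relation
    becomes an edge weighted by its relevance score, between a gene node
    (labelled by abbreviation, full name kept as an attribute) and a cell
    node. A node's size weight is the max (or sum) of its incident edge
    scores. Concepts shared between terms merge into one node. No
    self-edges; the graph is bipartite gene/cell.
    """
    params = params or QueryParams()
    graph = nx.Graph()

    def add_concept(concept: ConceptRecord) -> str:
        if concept.cui not in graph:
            label = (
                concept.abbreviation
                if concept.concept_class is EntityClass.GENE and concept.abbreviation
                else concept.canonical_name
            )
            graph.add_node(
                concept.cui,
                kind=concept.concept_class.value,
                label=label,
                full_name=concept.canonical_name,
                weight=0.0,
            )
        return concept.cui

    def add_edge(gene: ConceptRecord, cell: ConceptRecord, score: float) -> None:
        u, v = add_concept(gene), add_concept(cell)
        if not graph.has_edge(u, v):
            graph.add_edge(u, v, weight=score)

    for term in terms:
        for concept in resolve_query_term(term, deployment.gene_catalog, exact=params.exact):
            for hit in query_gene(deployment, concept.canonical_name, params):
                add_edge(concept, hit.concept, hit.score)
        for concept in resolve_query_term(term, deployment.cell_catalog, exact=params.exact):
            for hit in query_cell(deployment, concept.canonical_name, params):
                add_edge(hit.concept, concept, hit.score)

    for node in graph.nodes:
        scores = [graph.edges[e]["weight"] for e in graph.edges(node)]
        if scores:
            graph.nodes[node]["weight"] = max(scores) if node_weight == "max" else sum(scores)
    return graph


GraphFormat = Literal["graphml", "node-link-json"]


def export_graph(graph: nx.Graph, path: str, format: GraphFormat = "graphml") -> None:
    """Serialise a co-occurrence graph losslessly for external viewers."""
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "node-link-json":
        data = nx.node_link_data(graph, edges="edges")
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(data, handle, indent=1)
    else:
        raise ValueError(f"unsupported graph format: {format!r}")


def load_graph(path: str, format: GraphFormat = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph` (round-trip inverse)."""
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "node-link-json":
        with open(path, encoding="utf-8") as handle:
            return nx.node_link_graph(json.load(handle), edges="edges")
    raise ValueError(f"unsupported graph format: {format!r}")


def hits_to_frame(hits: Sequence[QueryHit], precision: int = 2) -> pd.DataFrame:
    """Ranked-table export mirroring the extended search-result layout."""
    return pd.DataFrame(
        [
            {
                "name": h.concept.canonical_name,
                "c_pmid": h.c_pmid,
                "c_total": h.c_total,
                "score": round(h.score, precision),
                "score_raw": h.score,
                "pmids": ";".join(str(p) for p in h.pmids),
            }
            for h in hits
        ],
        columns=["name", "c_pmid", "c_total", "score", "score_raw", "pmids"],
    )
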