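"""Benchmark procedure: marker selection, top-1 hit distance, database
comparison and per-cell-type summaries.

The benchmark asks: given the top differentially expressed genes of each
annotated cluster, how close does each database's top-ranked cell type for
each gene land to the cluster's reference cell type, measured on the
ontology distance metric? Two marker sources are compared — the literature
atlas and a curated marker database — plus their combination, which takes
the minimum distance over the databases that matched each gene; a gene
matched by only one database keeps that database's singular top-1 distance.

Marker genes per cluster are the top n (default 50) by the one-versus-rest
mean-expression ratio: (mean in cluster + eps) / (mean in the other
clusters + eps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Protocol, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph, term_distance
from .query_engine import Deployment, QueryParams, query_gene


class MarkerSource(Protocol):
    """Anything that can rank cell-type term ids for a gene symbol."""

    def top_cells(self, gene: str) -> list[str]:
        """Ranked cell-type term ids for ``gene``; empty when unmatched."""
        ...


class AtlasMarkerSource:
    """Adapter: the deployment atlas as a marker source.

    Cell CUIs in the deployment table are expected to be ontology term ids
    (as they are when concepts are normalised to the cell ontology); an
    optional ``cell_term_map`` translates otherwise.
    """

    def __init__(
        self,
        deployment: Deployment,
        params: QueryParams | None = None,
        cell_term_map: dict[str, str] | None = None,
    ) -> None:
        self.deployment = deployment
        self.params = params or QueryParams()
        self.cell_term_map = cell_term_map or {}

    def top_cells(self, gene: str) -> list[str]:
        hits = query_gene(self.deployment, gene, self.params)
        return [self.cell_term_map.get(h.concept.cui, h.concept.cui) for h in hits]


RankSource = Literal["file_order", "marker_count"]


class CuratedMarkerSource:
    """Adapter: a curated marker database as (cell term id -> genes).

    Curated databases carry no co-occurrence counts, so the top-1 choice
    among several matching cell types needs a rank source: ``file_order``
    (first listed wins) or ``marker_count`` (cell types with more markers
    rank first). This is an interpretation knob, not part of the data.
    """

    def __init__(
        self, markers: dict[str, list[str]], rank_source: RankSource = "file_order"
    ) -> None:
        self.markers = dict(markers)
        self.rank_source = rank_source
        self._order = {cell: i for i, cell in enumerate(self.markers)}

    @classmethod
    def from_tsv(cls, path: str, rank_source: RankSource = "file_order") -> "CuratedMarkerSource":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for column in ("cell_term_id", "gene_symbol"):
            if column not in frame.columns:
                raise ValueError(f"curated db {path} is missing column {column}")
        markers: dict[str, list[str]] = {}
        for row in frame.itertuples(index=False):
            markers.setdefault(row.cell_term_id, []).append(row.gene_symbol)
        return cls(markers, rank_source=rank_source)

    def top_cells(self, gene: str) -> list[str]:
        folded = gene.casefold()
        cells = [c for c, genes in self.markers.items() if any(g.casefold() == folded for g in genes)]
        if self.rank_source == "marker_count":
            cells.sort(key=lambda c: (-len(self.markers[c]), self._order[c]))
        else:
            cells.sort(key=lambda c: self._order[c])
        return cells


@dataclass
class EvalConfig:
    n_degs: int = 50
    min_pmids: int = 3
    pseudocount: float = 1e-9
    unreachable_policy: Literal["exclude", "penalize"] = "exclude"
    unreachable_penalty: int = 10

    def __post_init__(self) -> None:
        if self.n_degs < 1:
            raise ValueError("n_degs must be >= 1")


@dataclass
class EvalRecord:
    """One marker gene's top-1 hits and distances in both databases."""

    gene: str
    reference_cell: str
    top1_cell_a: str | None = None
    top1_cell_b: str | None = None
    dist_a: int | None = None
    dist_b: int | None = None

    @property
    def combined(self) -> int | None:
        """Minimum distance over the databases that matched this gene."""
        return combined_distance(self.dist_a, self.dist_b)


def select_top_degs(
    expr: pd.DataFrame, n: int = 50, pseudocount: float = 1e-9
) -> dict[str, list[str]]:
    """Top-n marker genes per cluster by the 1-versus-rest expression ratio.

    ``expr`` is a clusters x genes table of mean expression (values >= 0,
    at least two clusters). Genes are ranked per cluster by
    ``(mean_in + pseudocount) / (mean_rest + pseudocount)`` descending,
    ties broken by gene name ascending. Asking for more genes than exist
    returns all of them.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least two clusters for a 1-vs-rest ratio")
    if (expr.values < 0).any():
        raise ValueError("expression means must be non-negative")
    result: dict[str, list[str]] = {}
    totals = expr.sum(axis=0)
    k = expr.shape[0]
    for cluster in expr.index:
        mean_in = expr.loc[cluster]
        mean_rest = (totals - mean_in) / (k - 1)
        ratio = (mean_in + pseudocount) / (mean_rest + pseudocount)
        order = sorted(expr.columns, key=lambda g: (-ratio[g], g))
        result[cluster] = order[: min(n, len(order))]
    return result


def top1_distance(
    db: MarkerSource, ontology: OntologyGraph, gene: str, reference_cell: str
) -> tuple[str | None, int | None]:
    """Distance from a database's top-1 cell type for ``gene`` to the
    reference cell type; ``(None, None)`` when the gene has no hit.

    An unreachable ontology pair also yields distance ``None`` (the policy
    for those lives in the summary step).
    """
    if reference_cell not in ontology.graph:
        raise KeyError(f"reference cell type not in ontology: {reference_cell}")
    cells = db.top_cells(gene)
    if not cells:
        return None, None
    top1 = cells[0]
    if top1 not in ontology.graph:
        return top1, None
    return top1, term_distance(ontology, top1, reference_cell).distance


def combined_distance(d_a: int | None, d_b: int | None) -> int | None:
    """Minimum over the matched per-database distances.

    A gene exclusive to one database keeps that database's distance; a gene
    matched by neither stays unmatched (``None``).
    """
    matched = [d for d in (d_a, d_b) if d is not None]
    return min(matched) if matched else None


def categorize_gene_matches(
    genes: Sequence[str], db_a: MarkerSource, db_b: MarkerSource
) -> dict[str, int]:
    """Partition genes by hit/no-hit in each database.

    Returns counts ``{"a_only", "both", "b_only", "neither"}`` summing to
    the gene-list length.
    """
    counts = {"a_only": 0, "both": 0, "b_only": 0, "neither": 0}
    for gene in genes:
        in_a = bool(db_a.top_cells(gene))
        in_b = bool(db_b.top_cells(gene))
        if in_a and in_b:
            counts["both"] += 1
        elif in_a:
            counts["a_only"] += 1
        elif in_b:
            counts["b_only"] += 1
        else:
            counts["neither"] += 1
    return counts


def extension_fraction(a_only: int, neither: int) -> float:
    """Share of genes unannotated by the curated database that the atlas
    recovers: a_only / (a_only + neither)."""
    if a_only + neither == 0:
        return float("nan")
    return a_only / (a_only + neither)


def evaluate_markers(
    markers_by_cell: dict[str, list[str]],
    db_a: MarkerSource,
    db_b: MarkerSource,
    ontology: OntologyGraph,
) -> list[EvalRecord]:
    """Build one :class:`EvalRecord` per (reference cell type, marker gene)."""
    records = []
    for reference_cell, genes in markers_by_cell.items():
        for gene in genes:
            top1_a, dist_a = top1_distance(db_a, ontology, gene, reference_cell)
            top1_b, dist_b = top1_distance(db_b, ontology, gene, reference_cell)
            records.append(
                EvalRecord(
                    gene=gene,
                    reference_cell=reference_cell,
                    top1_cell_a=top1_a,
                    top1_cell_b=top1_b,
                    dist_a=dist_a,
                    dist_b=dist_b,
                )
            )
    return records


@dataclass
class CellTypeSummary:
    reference_cell: str
    mean: float
    sigma: float
    n: int
    degenerate: bool = False  # single record: 0-width band


SummaryMode = Literal["per_db_difference", "combined"]


def _effective(dist: int | None, config: EvalConfig) -> float | None:
    if dist is not None:
        return float(dist)
    if config.unreachable_policy == "penalize":
        return float(config.unreachable_penalty)
    return None


def summarize_by_celltype(
    records: Sequence[EvalRecord],
    mode: SummaryMode = "combined",
    config: EvalConfig | None = None,
) -> list[CellTypeSummary]:
    """Per reference cell type: mean and 1-sigma band of either the
    per-database distance difference (dist_a - dist_b, over genes matched in
    both) or the combined distance (over genes matched in at least one).

    Sigma is the sample standard deviation (n-1 denominator); a cell type
    with a single contributing record gets a 0-width band flagged
    degenerate, and one with no contributing records is omitted.
    """
    config = config or EvalConfig()
    grouped: dict[str, list[float]] = {}
    for record in records:
        if mode == "per_db_difference":
            d_a = _effective(record.dist_a, config)
            d_b = _effective(record.dist_b, config)
            if d_a is None or d_b is None:
                continue
            value = d_a - d_b
        elif mode == "combined":
            combined = record.combined
            value = _effective(combined, config) if combined is not None else None
            if value is None:
                continue
        else:
            raise ValueError(f"unknown summary mode: {mode!r}")
        grouped.setdefault(record.reference_cell, []).append(value)
    summaries = []
    for cell in sorted(grouped):
        values = grouped[cell]
        n = len(values)
        mean = float(np.mean(values))
        if n > 1:
            sigma = float(np.std(values, ddof=1))
            degenerate = False
        else:
            sigma, degenerate = 0.0, True
        summaries.append(CellTypeSummary(cell, mean, sigma, n, degenerate))
    return summaries


def records_to_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Evaluation report as a flat table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "reference_cell": r.reference_cell,
                "top1_cell_a": r.top1_cell_a or "",
                "top1_cell_b": r.top1_cell_b or "",
                "dist_a": r.dist_a if r.dist_a is not None else math.nan,
                "dist_b": r.dist_b if r.dist_b is not None else math.nan,
                "combined": r.combined if r.combined is not None else math.nan,
            }
            for r in records
        ],
        columns=["gene", "reference_cell", "top1_cell_a", "top1_cell_b", "dist_a", "dist_b", "combined"],
    )
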