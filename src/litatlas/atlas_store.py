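"""Evidence store and aggregation: production table -> deployment table.

The production store keeps one evidence row per (gene, cell type, article)
triple together with a processed-article log, so re-ingesting a batch is
idempotent and incremental updates stay consistent. Aggregation groups
evidence by concept pair into the deployment table: ``c_pmid`` distinct
supporting articles and ``c_total`` summed per-article co-occurrence weight.
The deployment filter then drops weakly supported pairs (by default a pair
must be mentioned by at least three distinct articles).

The per-article co-occurrence weight is configurable because the literature
source does not pin it down: ``min`` (default) uses min(gene mentions, cell
mentions) in the article, which bounds inflation from one hyper-mentioned
entity; ``product`` counts every mention pair; ``binary`` counts one per
article.
"""

from __future__ import annotations

import sqlite3
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import pandas as pd

from .corpus_io import AnnotatedArticle, EntityClass

SCHEMA_VERSION = "1"

CooccurrenceStrategy = Literal["min", "product", "binary"]


@dataclass(frozen=True)
class RelationEvidence:
    """One article's co-occurrence contribution for one concept pair."""

    gene_cui: str
    cell_cui: str
    pmid: int
    pair_count: int

    def __post_init__(self) -> None:
        if self.pair_count < 1:
            raise ValueError("pair_count must be >= 1")


@dataclass
class AggregatedRelation:
    """A gene x cell-type pair aggregated over all supporting articles."""

    gene_cui: str
    cell_cui: str
    c_pmid: int
    c_total: int
    score: float | None = None
    pmids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.c_pmid < 1:
            raise ValueError("c_pmid must be >= 1")
        if self.c_total < self.c_pmid:
            raise ValueError("c_total must be >= c_pmid (each article contributes >= 1)")


@dataclass
class IngestReport:
    inserted: int = 0
    skipped: int = 0
    skipped_pmids: list[int] = field(default_factory=list)


def compute_article_cooccurrences(
    article: AnnotatedArticle, strategy: CooccurrenceStrategy = "min"
) -> list[RelationEvidence]:
    """Derive per-article evidence rows from an article's filtered mentions.

    Expects mentions already filtered to catalog-mapped gene and cell-type
    concepts. Emits one row per distinct (gene CUI, cell CUI) pair present,
    weighted by the chosen strategy; an article lacking either class yields
    nothing.
    """
    gene_counts: Counter[str] = Counter()
    cell_counts: Counter[str] = Counter()
    for m in article.mentions:
        if m.concept_id is None:
            continue
        if m.entity_class is EntityClass.GENE:
            gene_counts[m.concept_id] += 1
        elif m.entity_class is EntityClass.CELL_TYPE:
            cell_counts[m.concept_id] += 1
    evidence = []
    for gene_cui in sorted(gene_counts):
        for cell_cui in sorted(cell_counts):
            g, c = gene_counts[gene_cui], cell_counts[cell_cui]
            if strategy == "min":
                weight = min(g, c)
            elif strategy == "product":
                weight = g * c
            elif strategy == "binary":
                weight = 1
            else:
                raise ValueError(f"unknown co-occurrence strategy: {strategy!r}")
            evidence.append(RelationEvidence(gene_cui, cell_cui, article.pmid, weight))
    return evidence


class AtlasStore:
    """Single-file embedded relation store (SQLite).

    Two production tables — ``evidence`` and the ``processed_articles`` log —
    plus a ``meta`` row carrying the schema version. Use ``path=":memory:"``
    for ephemeral stores.
    """

    def __init__(self, path: str = ":memory:") -> None:
        self.path = path
        self._conn = sqlite3.connect(path)
        self._init_schema()

    def _init_schema(self) -> None:
        cur = self._conn.cursor()
        cur.executescript(
            """
            CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE IF NOT EXISTS evidence (
                gene_cui TEXT NOT NULL,
                cell_cui TEXT NOT NULL,
                pmid INTEGER NOT NULL,
                pair_count INTEGER NOT NULL CHECK (pair_count >= 1),
                PRIMARY KEY (gene_cui, cell_cui, pmid)
            );
            CREATE TABLE IF NOT EXISTS processed_articles (
                pmid INTEGER PRIMARY KEY,
                journal TEXT,
                pub_date TEXT
            );
            """
        )
        cur.execute(
            "INSERT OR IGNORE INTO meta (key, value) VALUES ('schema_version', ?)",
            (SCHEMA_VERSION,),
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "AtlasStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def schema_version(self) -> str:
        row = self._conn.execute(
            "SELECT value FROM meta WHERE key = 'schema_version'"
        ).fetchone()
        return row[0]

    def processed_pmids(self) -> set[int]:
        return {r[0] for r in self._conn.execute("SELECT pmid FROM processed_articles")}

    def evidence_rows(self) -> list[RelationEvidence]:
        return [
            RelationEvidence(*row)
            for row in self._conn.execute(
                "SELECT gene_cui, cell_cui, pmid, pair_count FROM evidence "
                "ORDER BY gene_cui, cell_cui, pmid"
            )
        ]


def ingest_articles(
    store: AtlasStore,
    articles: Iterable[AnnotatedArticle],
    strategy: CooccurrenceStrategy = "min",
) -> IngestReport:
    """Insert evidence for new articles; skip already-processed PMIDs.

    The whole batch is one transaction: a storage failure rolls it back.
    Re-ingesting the same articles is a no-op (idempotent), so the final
    store content does not depend on how a corpus is split into batches.
    """
    report = IngestReport()
    conn = store._conn
    try:
        with conn:
            seen = store.processed_pmids()
            for article in articles:
                if article.pmid in seen:
                    report.skipped += 1
                    report.skipped_pmids.append(article.pmid)
                    continue
                seen.add(article.pmid)
                conn.execute(
                    "INSERT INTO processed_articles (pmid, journal, pub_date) VALUES (?,?,?)",
                    (article.pmid, article.journal, article.pub_date),
                )
                for ev in compute_article_cooccurrences(article, strategy):
                    conn.execute(
                        "INSERT INTO evidence (gene_cui, cell_cui, pmid, pair_count) "
                        "VALUES (?,?,?,?)",
                        (ev.gene_cui, ev.cell_cui, ev.pmid, ev.pair_count),
                    )
                report.inserted += 1
    except sqlite3.Error:
        raise
    return report


def aggregate_to_deployment(store: AtlasStore) -> list[AggregatedRelation]:
    """Group evidence by concept pair into deployment rows.

    ``c_pmid`` counts distinct supporting articles, ``c_total`` sums the
    per-article weights; supporting PMIDs are kept as provenance. Rows come
    back in deterministic (gene_cui, cell_cui) order.
    """
    rows = []
    for gene_cui, cell_cui, c_pmid, c_total, pmids in store._conn.execute(
        "SELECT gene_cui, cell_cui, COUNT(DISTINCT pmid), SUM(pair_count), "
        "GROUP_CONCAT(pmid) FROM evidence "
        "GROUP BY gene_cui, cell_cui ORDER BY gene_cui, cell_cui"
    ):
        rows.append(
            AggregatedRelation(
                gene_cui=gene_cui,
                cell_cui=cell_cui,
                c_pmid=c_pmid,
                c_total=c_total,
                pmids=tuple(sorted(int(p) for p in pmids.split(","))),
            )
        )
    return rows


def apply_deployment_filter(
    rows: Sequence[AggregatedRelation], min_pmids: int = 3, min_total: int = 1
) -> list[AggregatedRelation]:
    """Keep pairs with at least ``min_pmids`` distinct articles and
    ``min_total`` total co-occurrences; order preserved."""
    if min_pmids < 1 or min_total < 1:
        raise ValueError("min_pmids and min_total must be >= 1")
    return [r for r in rows if r.c_pmid >= min_pmids and r.c_total >= min_total]


def merge_incremental(
    base: Sequence[AggregatedRelation], delta: Sequence[AggregatedRelation]
) -> list[AggregatedRelation]:
    """Merge deployment rows aggregated over disjoint article sets.

    Counts add per pair; pairs unique to either side pass through. When both
    sides carry PMID provenance, any overlap refuses the merge — the inputs
    were not aggregated over disjoint corpora and counts would double.
    """
    merged: dict[tuple[str, str], AggregatedRelation] = {
        (r.gene_cui, r.cell_cui): replace(r) for r in base
    }
    for r in delta:
        key = (r.gene_cui, r.cell_cui)
        if key in merged:
            existing = merged[key]
            if existing.pmids and r.pmids:
                overlap = set(existing.pmids) & set(r.pmids)
                if overlap:
                    raise ValueError(
                        f"merge refused: overlapping PMID provenance for pair {key}: "
                        f"{sorted(overlap)[:5]}"
                    )
            merged[key] = AggregatedRelation(
                gene_cui=r.gene_cui,
                cell_cui=r.cell_cui,
                c_pmid=existing.c_pmid + r.c_pmid,
                c_total=existing.c_total + r.c_total,
                pmids=tuple(sorted((*existing.pmids, *r.pmids))),
            )
        else:
            merged[key] = replace(r)
    return [merged[k] for k in sorted(merged)]


def export_deployment_tsv(rows: Sequence[AggregatedRelation], path: str) -> None:
    """Write the deployment table as interchange TSV."""
    pd.DataFrame(
        [
            {
                "gene_cui": r.gene_cui,
                "cell_cui": r.cell_cui,
                "c_pmid": r.c_pmid,
                "c_total": r.c_total,
                "pmids": ";".join(str(p) for p in r.pmids),
            }
            for r in rows
        ],
        columns=["gene_cui", "cell_cui", "c_pmid", "c_total", "pmids"],
    ).to_csv(path, sep="\t", index=False)


def import_deployment_tsv(path: str) -> list[AggregatedRelation]:
    """Read a deployment table written by :func:`export_deployment_tsv`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for row in frame.itertuples(index=False):
        pmids = tuple(int(p) for p in str(row.pmids).split(";") if p) if "pmids" in frame.columns else ()
        rows.append(
            AggregatedRelation(
                gene_cui=row.gene_cui,
                cell_cui=row.cell_cui,
                c_pmid=int(row.c_pmid),
                c_total=int(row.c_total),
                pmids=pmids,
            )
        )
    return rows
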