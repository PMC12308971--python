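"""Synthetic corpora, ontologies, catalogs and expression tables.

Real inputs to the atlas are PubMed-scale annotated articles, the Cell
Ontology, concept catalogs and clustered scRNA-seq expression — none of
which can (or should) be downloaded to test the pipeline. The generators
here produce miniature stand-ins with known ground truth: a corpus with
planted gene-to-cell-type associations, a random rooted is_a DAG, matching
gene/cell catalogs, a curated marker-database stand-in, and a cluster-mean
expression table with planted markers. Everything is deterministic under a
seed, byte for byte, and is emitted both as in-memory objects and in the
on-disk interchange formats so the I/O layers are exercised end to end.

The default corpus parameters are chosen as a desk-scale caricature of the
real setting: a few hundred abstracts, each focused on one cell type,
mentioning that cell type's planted marker genes far more often than
background pairs. Mention counts are Poisson draws whose means follow the
association matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concept_mapping import ConceptCatalog, ConceptRecord
from .corpus_io import AnnotatedArticle, EntityClass, EntityMention
from .ontology import OntologyGraph


@dataclass
class SyntheticTruth:
    """Generator parameters plus the planted association matrix.

    ``association[(gene_cui, cell_cui)]`` is a mention-rate multiplier
    applied to ``base_rate`` when the article's focal cell type is
    ``cell_cui``; unplanted pairs co-mention at ``noise_rate``.
    """

    n_articles: int = 400
    n_genes: int = 20
    n_cells: int = 5
    base_rate: float = 1.5
    planted_multiplier: float = 4.0
    noise_rate: float = 0.02
    seed: int = 0
    association: dict[tuple[str, str], float] = field(default_factory=dict)
    # bookkeeping filled by generate_corpus
    planted_cell_of_gene: dict[str, str] = field(default_factory=dict)
    total_pair_mentions: int = 0

    def gene_cui(self, i: int) -> str:
        return f"G{i + 1:04d}"

    def cell_cui(self, i: int) -> str:
        return f"CL:{9000000 + i + 1}"


def _default_association(truth: SyntheticTruth) -> None:
    """Plant each gene on one cell type, round-robin."""
    if truth.association:
        return
    for i in range(truth.n_genes):
        gene = truth.gene_cui(i)
        cell = truth.cell_cui(i % truth.n_cells)
        truth.association[(gene, cell)] = truth.planted_multiplier
        truth.planted_cell_of_gene[gene] = cell


def generate_catalogs(truth: SyntheticTruth) -> tuple[ConceptCatalog, ConceptCatalog]:
    """Gene and cell-type catalogs covering the generator's concept space."""
    genes = ConceptCatalog(concept_class=EntityClass.GENE)
    for i in range(truth.n_genes):
        cui = truth.gene_cui(i)
        genes.add(
            ConceptRecord(
                cui=cui,
                concept_class=EntityClass.GENE,
                canonical_name=f"synthetic gene {i + 1}",
                abbreviation=f"SYG{i + 1}",
                synonyms=(f"syg-{i + 1}",),
                gene_type="protein-coding",
            )
        )
    cells = ConceptCatalog(concept_class=EntityClass.CELL_TYPE)
    for i in range(truth.n_cells):
        cui = truth.cell_cui(i)
        cells.add(
            ConceptRecord(
                cui=cui,
                concept_class=EntityClass.CELL_TYPE,
                canonical_name=f"synthetic cell type {i + 1}",
                synonyms=(f"sct{i + 1}",),
            )
        )
    return genes, cells


def generate_corpus(truth: SyntheticTruth) -> list[AnnotatedArticle]:
    """Draw an annotated corpus from the planted association model.

    Each article gets a focal cell type (round-robin, so coverage is even);
    the focal cell is mentioned 1 + Poisson(1) times, each gene a Poisson
    number of times with mean ``base_rate * multiplier`` if planted on the
    focal cell and ``noise_rate`` otherwise; non-focal cells appear at
    ``noise_rate``. Mentions are laid out in a synthetic abstract so span
    offsets are real. The truth object's bookkeeping (planted map, total
    pair-mention budget under the ``min`` counting rule) is filled in.
    """
    _default_association(truth)
    rng = np.random.default_rng(truth.seed)
    articles: list[AnnotatedArticle] = []
    truth.total_pair_mentions = 0

    gene_names = {truth.gene_cui(i): f"SYG{i + 1}" for i in range(truth.n_genes)}
    cell_names = {truth.cell_cui(i): f"sct{i + 1}" for i in range(truth.n_cells)}

    for a in range(truth.n_articles):
        pmid = a + 1
        focal = truth.cell_cui(a % truth.n_cells)
        counts: dict[tuple[EntityClass, str], int] = {}
        counts[(EntityClass.CELL_TYPE, focal)] = 1 + int(rng.poisson(1.0))
        for j in range(truth.n_cells):
            cell = truth.cell_cui(j)
            if cell == focal:
                continue
            k = int(rng.poisson(truth.noise_rate))
            if k:
                counts[(EntityClass.CELL_TYPE, cell)] = k
        for i in range(truth.n_genes):
            gene = truth.gene_cui(i)
            mult = truth.association.get((gene, focal))
            mean = truth.base_rate * mult if mult is not None else truth.noise_rate
            k = int(rng.poisson(mean))
            if k:
                counts[(EntityClass.GENE, gene)] = k

        title = f"Synthetic abstract {pmid}"
        tokens: list[tuple[str, EntityClass, str]] = []
        for (klass, cui), k in sorted(counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            surface = gene_names[cui] if klass is EntityClass.GENE else cell_names[cui]
            tokens.extend((surface, klass, cui) for _ in range(k))
        mentions: list[EntityMention] = []
        offset = len(title) + 1  # abstract starts after the title newline
        abstract_parts: list[str] = []
        for surface, klass, cui in tokens:
            start = offset
            end = start + len(surface)
            mentions.append(
                EntityMention(
                    surface_text=surface,
                    entity_class=klass,
                    concept_id=cui,
                    span_start=start,
                    span_end=end,
                )
            )
            abstract_parts.append(surface)
            offset = end + 1  # single-space separator
        articles.append(
            AnnotatedArticle(
                pmid=pmid,
                title=title,
                abstract=" ".join(abstract_parts),
                journal="Synthetic Journal",
                pub_date="2024-01-01",
                mentions=mentions,
            )
        )
        # bookkeeping under the default min-counting rule
        gene_counts = {c: k for (kl, c), k in counts.items() if kl is EntityClass.GENE}
        cell_counts = {c: k for (kl, c), k in counts.items() if kl is EntityClass.CELL_TYPE}
        for gk in gene_counts.values():
            for ck in cell_counts.values():
                truth.total_pair_mentions += min(gk, ck)
    return articles


def generate_cell_ontology(truth: SyntheticTruth) -> OntologyGraph:
    """Minimal ontology over the corpus's cell types: one root, all
    synthetic cell types as sibling subclasses (pairwise distance 2)."""
    ontology = OntologyGraph()
    root = "CL:9000000"
    ontology.add_term(root, "synthetic cell")
    for i in range(truth.n_cells):
        cui = truth.cell_cui(i)
        ontology.add_term(cui, f"synthetic cell type {i + 1}", synonyms=(f"sct{i + 1}",))
        ontology.add_is_a(cui, root)
    return ontology


FIG_TRIO_PRESET = "anucleate-trio"


def generate_toy_ontology(
    n_terms: int = 20, max_parents: int = 2, seed: int = 0, preset: str | None = None
) -> OntologyGraph:
    """Random rooted is_a DAG, acyclic by construction.

    ``preset="anucleate-trio"`` instead returns the fixed three-term
    fixture — an "anucleate cell" superclass with "corneocyte" and
    "platelet" subclasses — whose child/parent distance is 1 and whose
    sibling distance is 2.
    """
    ontology = OntologyGraph()
    if preset == FIG_TRIO_PRESET:
        ontology.add_term("CL:0000225", "anucleate cell")
        ontology.add_term("CL:0002153", "corneocyte")
        ontology.add_term("CL:0000233", "platelet")
        ontology.add_is_a("CL:0002153", "CL:0000225")
        ontology.add_is_a("CL:0000233", "CL:0000225")
        return ontology
    if preset is not None:
        raise ValueError(f"unknown ontology preset: {preset!r}")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"CL:{8000000 + i}" for i in range(n_terms)]
    for i, term_id in enumerate(ids):
        ontology.add_term(term_id, f"toy cell type {i}", synonyms=(f"tct{i}",))
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.integers(0, max_parents))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            ontology.add_is_a(ids[i], ids[int(p)])  # edges only to earlier terms: acyclic
    return ontology


def generate_expression_matrix(
    n_clusters: int = 5,
    n_genes: int = 100,
    markers_per_cluster: int = 5,
    effect: float = 10.0,
    seed: int = 0,
):
    """Cluster-mean expression table with planted marker genes.

    Background means are drawn from a log-normal distribution shared across
    clusters; each cluster's planted markers are multiplied by ``effect``
    in that cluster only. Returns ``(frame, labels, planted)`` where
    ``frame`` is clusters x genes (pandas), ``labels`` maps cluster names to
    toy-ontology term ids and ``planted`` maps cluster names to their marker
    gene lists. ``effect=1`` is the null model.
    """
    import pandas as pd

    if markers_per_cluster * n_clusters > n_genes:
        raise ValueError("need markers_per_cluster * n_clusters <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"SYG{i + 1}" for i in range(n_genes)]
    clusters = [f"cluster{c + 1}" for c in range(n_clusters)]
    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    matrix = np.tile(base, (n_clusters, 1)) * rng.lognormal(0.0, 0.1, size=(n_clusters, n_genes))
    planted: dict[str, list[str]] = {}
    for c in range(n_clusters):
        start = c * markers_per_cluster
        marker_idx = list(range(start, start + markers_per_cluster))
        matrix[c, marker_idx] *= effect
        planted[clusters[c]] = [genes[i] for i in marker_idx]
    labels = {clusters[c]: f"CL:{9000000 + (c % n_clusters) + 1}" for c in range(n_clusters)}
    frame = pd.DataFrame(matrix, index=clusters, columns=genes)
    return frame, labels, planted


def generate_expression_from_truth(
    truth: SyntheticTruth, effect: float = 10.0, seed: int | None = None
):
    """Cluster-mean expression table aligned with the corpus truth.

    One cluster per synthetic cell type; each gene is elevated by ``effect``
    in the cluster of the cell type it was planted on, so the expression
    markers and the literature associations tell the same story. Returns
    ``(frame, labels, planted)`` like :func:`generate_expression_matrix`,
    with cluster labels mapping onto the corpus cell term ids.
    """
    import pandas as pd

    _default_association(truth)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    genes = [f"SYG{i + 1}" for i in range(truth.n_genes)]
    clusters = [f"cluster{c + 1}" for c in range(truth.n_cells)]
    base = rng.lognormal(mean=0.0, sigma=0.5, size=truth.n_genes)
    matrix = np.tile(base, (truth.n_cells, 1)) * rng.lognormal(
        0.0, 0.1, size=(truth.n_cells, truth.n_genes)
    )
    labels = {clusters[c]: truth.cell_cui(c) for c in range(truth.n_cells)}
    cluster_of_cell = {truth.cell_cui(c): c for c in range(truth.n_cells)}
    planted: dict[str, list[str]] = {c: [] for c in clusters}
    for i in range(truth.n_genes):
        cell = truth.planted_cell_of_gene[truth.gene_cui(i)]
        c = cluster_of_cell[cell]
        matrix[c, i] *= effect
        planted[clusters[c]].append(genes[i])
    frame = pd.DataFrame(matrix, index=clusters, columns=genes)
    return frame, labels, planted


def generate_curated_db(
    truth: SyntheticTruth,
    coverage: float = 0.6,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Curated marker-database stand-in: cell term id -> marker gene symbols.

    Covers a random ``coverage`` fraction of the planted gene-cell
    assignments, emulating a high-quality but incomplete hand-curated
    database alongside the literature atlas.
    """
    _default_association(truth)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    gene_abbr = {truth.gene_cui(i): f"SYG{i + 1}" for i in range(truth.n_genes)}
    db: dict[str, list[str]] = {}
    for gene, cell in sorted(truth.planted_cell_of_gene.items()):
        if rng.random() < coverage:
            db.setdefault(cell, []).append(gene_abbr[gene])
    return db


def write_curated_db_tsv(db: dict[str, list[str]], path: str) -> None:
    """Write a curated marker database as (cell term id, gene symbol) TSV."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("cell_term_id\tgene_symbol\n")
        for cell in sorted(db):
            for gene in db[cell]:
                handle.write(f"{cell}\t{gene}\n")
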