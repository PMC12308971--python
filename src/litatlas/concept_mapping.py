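"""Offline concept catalogs: CUI and name normalisation for genes and cells.

The live pipeline this emulates resolves gene CUIs against NCBI Gene and
cell-type CUIs against the Cell Ontology through an ontology lookup service.
Here both are replaced by offline TSV catalogs behind a single resolver
contract (id or name -> ConceptRecord), so everything runs with no network;
a live resolver can be slotted in behind the same surface later.

Matching is case-insensitive and exact (no stemming, no fuzzy matching):
name standardisation, not free-text search, is the job of this layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .corpus_io import EntityClass, EntityMention

REQUIRED_COLUMNS = ("cui", "canonical_name", "abbreviation", "gene_type", "synonyms")


@dataclass(frozen=True)
class ConceptRecord:
    """One standardised concept: a gene or a cell type."""

    cui: str
    concept_class: EntityClass
    canonical_name: str
    abbreviation: str | None = None
    synonyms: tuple[str, ...] = ()
    gene_type: str | None = None

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("cui must be non-empty")
        if not self.canonical_name:
            raise ValueError(f"canonical_name must be non-empty (cui {self.cui})")

    @property
    def names(self) -> tuple[str, ...]:
        extras = (self.abbreviation,) if self.abbreviation else ()
        return (self.canonical_name, *extras, *self.synonyms)


@dataclass(frozen=True)
class UnmappedMarker:
    """Returned when a mention cannot be resolved to a unique concept."""

    reason: str
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


@dataclass
class ConceptCatalog:
    """CUI-keyed concept collection with a case-folded name index."""

    concept_class: EntityClass
    records: dict[str, ConceptRecord] = field(default_factory=dict)
    name_index: dict[str, set[str]] = field(default_factory=dict)

    def add(self, record: ConceptRecord) -> None:
        if record.cui in self.records:
            raise ValueError(f"duplicate cui in catalog: {record.cui}")
        self.records[record.cui] = record
        for name in record.names:
            self.name_index.setdefault(name.casefold(), set()).add(record.cui)

    @property
    def cuis(self) -> frozenset[str]:
        return frozenset(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_catalog(path: str, concept_class: EntityClass) -> ConceptCatalog:
    """Load a concept catalog from a TSV file.

    Expected header columns: ``cui``, ``canonical_name``, ``abbreviation``,
    ``gene_type``, ``synonyms`` (pipe-separated list; may be blank). Cell
    catalogs leave the gene-specific columns blank. A duplicate CUI or a
    missing required column fails the load, naming the offender.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"catalog {path} is missing required column(s): {', '.join(missing)}")
    catalog = ConceptCatalog(concept_class=concept_class)
    for row in frame.itertuples(index=False):
        synonyms = tuple(s for s in str(row.synonyms).split("|") if s)
        catalog.add(
            ConceptRecord(
                cui=row.cui,
                concept_class=concept_class,
                canonical_name=row.canonical_name,
                abbreviation=row.abbreviation or None,
                synonyms=synonyms,
                gene_type=row.gene_type or None,
            )
        )
    return catalog


def save_catalog(catalog: ConceptCatalog, path: str) -> None:
    """Write a catalog back to the TSV interchange layout."""
    rows = [
        {
            "cui": r.cui,
            "canonical_name": r.canonical_name,
            "abbreviation": r.abbreviation or "",
            "gene_type": r.gene_type or "",
            "synonyms": "|".join(r.synonyms),
        }
        for r in catalog.records.values()
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


def normalize_mention(
    mention: EntityMention, catalog: ConceptCatalog
) -> ConceptRecord | UnmappedMarker:
    """Resolve a mention to a catalog record.

    The annotator-normalised concept id is the primary key; if it is absent,
    a case-insensitive exact match on the surface text is attempted. An
    ambiguous surface form (matching several CUIs) is never silently
    resolved — it returns an :class:`UnmappedMarker` with the candidates.
    """
    if mention.entity_class is not catalog.concept_class:
        raise ValueError(
            f"mention class {mention.entity_class.value} does not match "
            f"catalog class {catalog.concept_class.value}"
        )
    if mention.concept_id is not None and mention.concept_id in catalog.records:
        return catalog.records[mention.concept_id]
    cuis = catalog.name_index.get(mention.surface_text.casefold(), set())
    if len(cuis) == 1:
        return catalog.records[next(iter(cuis))]
    if len(cuis) > 1:
        return UnmappedMarker(
            reason=f"surface text {mention.surface_text!r} is ambiguous",
            ambiguous=True,
            candidates=tuple(sorted(cuis)),
        )
    return UnmappedMarker(reason=f"no catalog match for {mention.surface_text!r}")


def resolve_query_term(
    term: str, catalog: ConceptCatalog, exact: bool = True
) -> list[ConceptRecord]:
    """Resolve a free-text query term to catalog records.

    ``exact=True`` returns records with a case-insensitive exact match on any
    indexed name (canonical name, abbreviation, or synonym); ``exact=False``
    returns records where the term is a case-insensitive substring of any
    indexed name. Results are sorted by canonical name. Exact results are
    always a subset of substring results for the same term.
    """
    if not term:
        raise ValueError("query term must be non-empty")
    folded = term.casefold()
    if exact:
        cuis = set(catalog.name_index.get(folded, set()))
    else:
        cuis = {
            cui for name, name_cuis in catalog.name_index.items() if folded in name
            for cui in name_cuis
        }
    return sorted((catalog.records[c] for c in cuis), key=lambda r: r.canonical_name)
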