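import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from litatlas import (
    AtlasStore,
    Deployment,
    EntityClass,
    aggregate_to_deployment,
    apply_deployment_filter,
    ingest_articles,
)
from litatlas.atlas_store import AggregatedRelation
from litatlas.concept_mapping import ConceptCatalog, ConceptRecord
from litatlas.synthetic_data import SyntheticTruth, generate_catalogs, generate_corpus

#: Published worked example: counts behind the ranked result table for the
#: gene query "alpha-1-B glycoprotein" (A1BG), with 2-decimal display scores.
TABLE1_ROWS = [
    ("B cell", 110, 222, 4.79),
    ("Platelet", 64, 204, 4.17),
    ("Enucleate erythrocyte", 67, 188, 4.15),
    ("T cell", 73, 129, 3.93),
    ("Neutrophil", 35, 80, 2.94),
]


@pytest.fixture(scope="session")
def table1_deployment() -> Deployment:
    """Deployment store whose aggregated counts equal the worked example."""
    genes = ConceptCatalog(concept_class=EntityClass.GENE)
    genes.add(
        ConceptRecord(
            cui="NCBIGene:1",
            concept_class=EntityClass.GENE,
            canonical_name="alpha-1-B glycoprotein",
            abbreviation="A1BG",
            gene_type="protein-coding",
        )
    )
    cells = ConceptCatalog(concept_class=EntityClass.CELL_TYPE)
    rows = []
    for i, (name, c_pmid, c_total, _) in enumerate(TABLE1_ROWS):
        cui = f"CL:{1000 + i}"
        cells.add(ConceptRecord(cui=cui, concept_class=EntityClass.CELL_TYPE, canonical_name=name))
        rows.append(AggregatedRelation("NCBIGene:1", cui, c_pmid, c_total))
    return Deployment(rows, genes, cells)


@pytest.fixture(scope="session")
def default_truth() -> SyntheticTruth:
    truth = SyntheticTruth(seed=7)
    truth.articles = generate_corpus(truth)  # type: ignore[attr-defined]
    return truth


@pytest.fixture(scope="session")
def synthetic_deployment(default_truth) -> Deployment:
    """Default synthetic corpus ingested, aggregated and filtered."""
    store = AtlasStore()
    ingest_articles(store, default_truth.articles)
    rows = apply_deployment_filter(aggregate_to_deployment(store))
    genes, cells = generate_catalogs(default_truth)
    return Deployment(rows, genes, cells)
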