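"""Marker selection, top-1 hit distances, database comparison, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from litatlas.evaluation import (
    AtlasMarkerSource,
    CuratedMarkerSource,
    EvalConfig,
    EvalRecord,
    categorize_gene_matches,
    combined_distance,
    evaluate_markers,
    extension_fraction,
    select_top_degs,
    summarize_by_celltype,
    top1_distance,
)
from litatlas.synthetic_data import (
    FIG_TRIO_PRESET,
    generate_cell_ontology,
    generate_expression_matrix,
    generate_toy_ontology,
)


class FakeSource:
    def __init__(self, mapping):
        self.mapping = mapping

    def top_cells(self, gene):
        return list(self.mapping.get(gene, []))


class TestSelectTopDegs:
    def test_exclusive_gene_ranks_first(self):
        expr = pd.DataFrame(
            [[10.0, 1.0, 1.0], [0.0, 1.0, 1.0]], index=["A", "B"], columns=["g1", "g2", "g3"]
        )
        assert select_top_degs(expr, n=1)["A"] == ["g1"]

    def test_uniform_table_breaks_ties_alphabetically(self):
        expr = pd.DataFrame(np.ones((3, 4)), index=list("ABC"), columns=["gd", "ga", "gc", "gb"])
        assert select_top_degs(expr, n=4)["B"] == ["ga", "gb", "gc", "gd"]

    def test_n_beyond_gene_count_returns_all(self):
        expr = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["A", "B"], columns=["g1", "g2"])
        assert len(select_top_degs(expr, n=50)["A"]) == 2

    def test_single_cluster_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["A"], columns=["g1"])
        with pytest.raises(ValueError):
            select_top_degs(expr)

    def test_planted_markers_recovered_before_background(self):
        expr, _, planted = generate_expression_matrix(
            n_clusters=4, n_genes=60, markers_per_cluster=5, effect=10.0, seed=3
        )
        degs = select_top_degs(expr, n=5)
        for cluster, markers in planted.items():
            assert set(degs[cluster]) == set(markers)

    def test_null_effect_gives_no_systematic_recovery(self):
        expr, _, planted = generate_expression_matrix(
            n_clusters=4, n_genes=200, markers_per_cluster=5, effect=1.0, seed=4
        )
        degs = select_top_degs(expr, n=5)
        overlap = sum(len(set(degs[c]) & set(m)) for c, m in planted.items())
        assert overlap <= 4  # chance level: 4 clusters x 5 picks x (5/200)

    def test_matches_direct_ratio_recomputation(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(
            rng.gamma(2.0, 1.0, size=(3, 30)),
            index=["A", "B", "C"],
            columns=[f"g{i:02d}" for i in range(30)],
        )
        eps = 1e-9
        degs = select_top_degs(expr, n=30, pseudocount=eps)
        for cluster in expr.index:
            rest = expr.drop(index=cluster).mean(axis=0)
            ratio = (expr.loc[cluster] + eps) / (rest + eps)
            expected = sorted(expr.columns, key=lambda g: (-ratio[g], g))
            assert degs[cluster] == expected


@pytest.fixture(scope="module")
def trio():
    return generate_toy_ontology(preset=FIG_TRIO_PRESET)


class TestTop1Distance:

    def test_exact_hit_is_zero(self, trio):
        source = FakeSource({"g": ["CL:0000233"]})
        assert top1_distance(source, trio, "g", "CL:0000233") == ("CL:0000233", 0)

    def test_parent_hit_is_one(self, trio):
        source = FakeSource({"g": ["CL:0000225"]})
        assert top1_distance(source, trio, "g", "CL:0000233") == ("CL:0000225", 1)

    def test_unmatched_gene(self, trio):
        assert top1_distance(FakeSource({}), trio, "g", "CL:0000233") == (None, None)

    def test_reference_absent_from_ontology_is_error(self, trio):
        with pytest.raises(KeyError):
            top1_distance(FakeSource({}), trio, "g", "CL:404")

    def test_only_top1_counts(self, trio):
        source = FakeSource({"g": ["CL:0002153", "CL:0000233"]})  # sibling first
        _, dist = top1_distance(source, trio, "g", "CL:0000233")
        assert dist == 2


class TestCombinedDistance:
    def test_min_of_matched(self):
        assert combined_distance(3, 1) == 1

    def test_exclusive_hit_used_alone(self):
        assert combined_distance(None, 2) == 2
        assert combined_distance(4, None) == 4

    def test_both_unmatched(self):
        assert combined_distance(None, None) is None

    def test_min_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            d_a = int(rng.integers(0, 9)) if rng.random() < 0.8 else None
            d_b = int(rng.integers(0, 9)) if rng.random() < 0.8 else None
            expected = min([d for d in (d_a, d_b) if d is not None], default=None)
            assert combined_distance(d_a, d_b) == expected

    def test_dominance_over_each_matched_distance(self):
        for d_a in (None, 0, 1, 5):
            for d_b in (None, 0, 2, 7):
                combined = combined_distance(d_a, d_b)
                if d_a is not None:
                    assert combined <= d_a
                if d_b is not None:
                    assert combined <= d_b


class TestCategorize:
    def test_explicit_assignment(self):
        db_a = FakeSource({"g1": ["c"], "g2": ["c"]})
        db_b = FakeSource({"g2": ["c"]})
        counts = categorize_gene_matches(["g1", "g2", "g3"], db_a, db_b)
        assert counts == {"a_only": 1, "both": 1, "b_only": 0, "neither": 1}

    def test_empty_gene_list(self):
        counts = categorize_gene_matches([], FakeSource({}), FakeSource({}))
        assert counts == {"a_only": 0, "both": 0, "b_only": 0, "neither": 0}

    def test_partition_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(120)]
        members_a = {g for g in genes if rng.random() < 0.5}
        members_b = {g for g in genes if rng.random() < 0.3}
        db_a = FakeSource({g: ["c"] for g in members_a})
        db_b = FakeSource({g: ["c"] for g in members_b})
        counts = categorize_gene_matches(genes, db_a, db_b)
        assert counts["both"] == len(members_a & members_b)
        assert counts["a_only"] == len(members_a - members_b)
        assert counts["b_only"] == len(members_b - members_a)
        assert counts["neither"] == len(set(genes) - members_a - members_b)
        assert sum(counts.values()) == len(genes)

    def test_extension_fraction(self):
        assert extension_fraction(274, 90) == pytest.approx(274 / 364)
        assert math.isnan(extension_fraction(0, 0))


class TestSummaries:
    def _records(self, values, cell="CL:1"):
        return [
            EvalRecord(gene=f"g{i}", reference_cell=cell, dist_a=a, dist_b=b)
            for i, (a, b) in enumerate(values)
        ]

    def test_difference_mean_and_sigma(self):
        records = self._records([(2, 1), (0, 1)])  # differences [1, -1]
        (summary,) = summarize_by_celltype(records, mode="per_db_difference")
        assert summary.mean == pytest.approx(0.0)
        assert summary.sigma == pytest.approx(math.sqrt(2))
        assert summary.n == 2

    def test_single_record_zero_width_band(self):
        (summary,) = summarize_by_celltype(self._records([(1, 3)]), mode="combined")
        assert summary.n == 1
        assert summary.sigma == 0.0
        assert summary.degenerate

    def test_unmatched_records_excluded_by_default(self):
        records = self._records([(None, None), (2, 3)])
        (summary,) = summarize_by_celltype(records, mode="combined")
        assert summary.n == 1
        assert summary.mean == pytest.approx(2.0)

    def test_cell_type_without_matched_records_omitted(self):
        records = self._records([(None, None)])
        assert summarize_by_celltype(records, mode="combined") == []

    def test_matches_formula_recomputation_on_simulated_records(self):
        rng = np.random.default_rng(11)
        records = []
        for i in range(300):
            cell = f"CL:{int(rng.integers(0, 5))}"
            d_a = int(rng.integers(0, 6)) if rng.random() < 0.9 else None
            d_b = int(rng.integers(0, 6)) if rng.random() < 0.7 else None
            records.append(EvalRecord(gene=f"g{i}", reference_cell=cell, dist_a=d_a, dist_b=d_b))
        summaries = {s.reference_cell: s for s in summarize_by_celltype(records, mode="combined")}
        grouped = {}
        for r in records:
            if r.combined is not None:
                grouped.setdefault(r.reference_cell, []).append(r.combined)
        assert set(summaries) == set(grouped)
        for cell, values in grouped.items():
            assert summaries[cell].mean == pytest.approx(np.mean(values))
            if len(values) > 1:
                assert summaries[cell].sigma == pytest.approx(np.std(values, ddof=1))

    def test_mean_combined_no_worse_than_either_db_on_intersection(self):
        rng = np.random.default_rng(13)
        records = self._records(
            [(int(rng.integers(0, 6)), int(rng.integers(0, 6))) for _ in range(100)]
        )
        mean_a = np.mean([r.dist_a for r in records])
        mean_b = np.mean([r.dist_b for r in records])
        mean_combined = np.mean([r.combined for r in records])
        assert mean_combined <= mean_a
        assert mean_combined <= mean_b


class TestMarkerSources:
    def test_curated_tsv_adapter_and_rank_sources(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "cell_term_id\tgene_symbol\n"
            "CL:1\tG1\nCL:1\tG2\nCL:1\tG3\n"
            "CL:2\tG1\n"
        )
        by_order = CuratedMarkerSource.from_tsv(str(path), rank_source="file_order")
        assert by_order.top_cells("g1") == ["CL:1", "CL:2"]  # case-insensitive
        by_count = CuratedMarkerSource.from_tsv(str(path), rank_source="marker_count")
        assert by_count.top_cells("G1")[0] == "CL:1"
        assert by_order.top_cells("G9") == []

    def test_atlas_adapter_end_to_end(self, default_truth, synthetic_deployment):
        """Full benchmark on the synthetic corpus: the atlas's top-1 cell for
        each planted gene sits at distance 0 from its reference."""
        ontology = generate_cell_ontology(default_truth)
        atlas = AtlasMarkerSource(synthetic_deployment)
        # reverse the catalog: query by abbreviation
        abbrev = {
            cui: rec.abbreviation
            for cui, rec in synthetic_deployment.gene_catalog.records.items()
        }
        markers_by_cell = {}
        for gene_cui, cell_cui in default_truth.planted_cell_of_gene.items():
            markers_by_cell.setdefault(cell_cui, []).append(abbrev[gene_cui])
        curated = CuratedMarkerSource({})
        records = evaluate_markers(markers_by_cell, atlas, curated, ontology)
        assert records
        matched = [r for r in records if r.dist_a is not None]
        assert len(matched) / len(records) >= 0.95
        assert np.mean([r.dist_a for r in matched]) <= 0.1
        for r in records:  # dominance invariant on every record
            if r.combined is not None:
                for d in (r.dist_a, r.dist_b):
                    if d is not None:
                        assert r.combined <= d


def test_eval_config_validation():
    with pytest.raises(ValueError):
        EvalConfig(n_degs=0)
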