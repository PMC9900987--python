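"""z-scoring, hierarchical clustering, and co-expression gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from oracles import brute_agglomerative_merges, brute_gate, linkage_merge_sets
from scmst.clustermap import (
    GENE_MODULES,
    GeneModule,
    annotate_clusters,
    annotations_from_json,
    annotations_to_json,
    gate_coexpression,
    hierarchical_cluster,
    zscore,
    zscore_through_genes,
)
from scmst.errors import ValidationError
from scmst.quantify import CountMatrix


def _matrix(counts, genes=None, stages=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    n = counts.shape[1]
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "fov": 0,
            "section": 0,
            "stage": stages if stages is not None else ["s1"] * n,
            "z": 0.0, "y": 0.0, "x": 0.0,
            "volume_voxels": 1,
        }
    )
    return CountMatrix(counts, genes, cells)


class TestZScore:
    def test_two_cell_group_gives_unit_scores(self):
        zm = zscore(_matrix([[1, 3]]), mode="per_stage")
        assert np.allclose(zm.z, [[-1.0, 1.0]])

    def test_constant_gene_zeroed_and_flagged(self):
        zm = zscore(_matrix([[5, 5, 5], [1, 2, 3]]))
        assert (zm.z[0] == 0).all()
        assert ("g0", "s1") in zm.zero_variance
        assert ("g1", "s1") not in zm.zero_variance

    def test_moments_within_groups(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (30, 500))
        stages = ["a"] * 250 + ["b"] * 250
        zm = zscore(_matrix(counts, stages=stages), mode="per_stage")
        for stage in ("a", "b"):
            sel = np.array(stages) == stage
            sub = zm.z[:, sel]
            assert np.abs(sub.mean(axis=1)).max() < 1e-9
            assert np.abs(sub.std(axis=1) - 1).max() < 1e-9

    def test_cross_stage_pools_everything(self):
        counts = np.arange(12).reshape(2, 6)
        zm = zscore(_matrix(counts, stages=["a"] * 3 + ["b"] * 3),
                    mode="cross_stage")
        assert np.abs(zm.z.mean(axis=1)).max() < 1e-9
        assert len(set(zm.grouping)) == 1

    def test_through_genes_standardizes_cell_profiles(self):
        rng = np.random.default_rng(1)
        zm = zscore(_matrix(rng.poisson(8, (20, 40))), mode="cross_stage")
        tg = zscore_through_genes(zm)
        assert np.abs(tg.z.mean(axis=0)).max() < 1e-9
        assert np.abs(tg.z.std(axis=0) - 1).max() < 1e-9

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            zscore(_matrix(np.zeros((3, 0), dtype=int)))

    def test_partial_grouping_rejected(self):
        with pytest.raises(ValidationError, match="cover"):
            zscore(_matrix([[1, 2, 3]]), grouping=np.array([0, 1]))


class TestHierarchical:
    def test_single_cluster(self):
        zm = zscore(_matrix(np.random.default_rng(0).poisson(5, (4, 10))))
        asg = hierarchical_cluster(zm, 1)
        assert set(asg.assignment) == {1}

    def test_n_clusters_equals_n_cells_gives_singletons(self):
        zm = zscore(_matrix(np.random.default_rng(1).poisson(5, (4, 8))))
        asg = hierarchical_cluster(zm, 8)
        assert len(set(asg.assignment)) == 8

    def test_ward_with_correlation_rejected(self):
        zm = zscore(_matrix([[1, 2, 3]]))
        with pytest.raises(ValidationError, match="ward"):
            hierarchical_cluster(zm, 2, metric="correlation", linkage="ward")

    @pytest.mark.parametrize("metric", ["euclidean", "correlation"])
    def test_five_cell_merge_sequence_matches_brute_force(self, metric):
        rng = np.random.default_rng(7)
        counts = rng.poisson(20, (6, 5))
        zm = zscore(_matrix(counts), mode="cross_stage")
        asg = hierarchical_cluster(zm, 1, metric=metric, linkage="average")
        got = linkage_merge_sets(asg.linkage_matrix, 5)
        expected = brute_agglomerative_merges(zm.z.T, metric=metric)
        assert got == expected

    def test_planted_programs_recovered(self, tiny_counts):
        cm, subpop = tiny_counts
        zm = zscore(cm, mode="cross_stage")
        asg = hierarchical_cluster(zm, 4)
        truth = subpop.loc[asg.assignment.index]
        assert adjusted_rand_score(truth, asg.assignment) >= 0.9

    def test_leaf_order_covers_all_cells(self, tiny_counts):
        cm, _ = tiny_counts
        zm = zscore(cm, mode="cross_stage")
        asg = hierarchical_cluster(zm, 4)
        assert sorted(asg.leaf_order) == sorted(cm.cells["cell_id"])


class TestGate:
    def test_strict_inequality_excludes_zero(self):
        zm = zscore(_matrix([[1, 2, 30]]))
        zm.z = np.array([[-0.2, 0.0, 1.5]])
        res = gate_coexpression(zm, GeneModule("m", ["g0"]))
        assert res.cell_ids == {3}

    def test_intersection_semantics(self):
        zm = zscore(_matrix(np.ones((3, 2), dtype=int)))
        zm.z = np.array([[0.5, 2.0], [0.5, 2.0], [0.5, -0.1]])
        res = gate_coexpression(zm, GeneModule("m", ["g0", "g1", "g2"]))
        assert res.cell_ids == {1}

    def test_empty_module_rejected(self):
        zm = zscore(_matrix([[1, 2]]))
        with pytest.raises(ValidationError, match="empty"):
            gate_coexpression(zm, GeneModule("m", []))

    def test_missing_gene_named_in_error(self):
        zm = zscore(_matrix([[1, 2]]))
        with pytest.raises(ValidationError, match="Nanog"):
            gate_coexpression(zm, GeneModule("m", ["Nanog"]))

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_intersection(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_cells = 6, 30
        zm = zscore(_matrix(rng.poisson(5, (n_genes, n_cells))),
                    mode="cross_stage")
        module = GeneModule("m", [f"g{i}" for i in range(3)])
        res = gate_coexpression(zm, module)
        expected = brute_gate(
            zm.z, zm.genes, zm.cells["cell_id"].to_numpy(), module.genes
        )
        assert res.cell_ids == expected

    def test_monotone_adding_gene_never_grows_gate(self):
        rng = np.random.default_rng(5)
        zm = zscore(_matrix(rng.poisson(5, (4, 50))), mode="cross_stage")
        small = gate_coexpression(zm, GeneModule("m", ["g0", "g1"]))
        big = gate_coexpression(zm, GeneModule("m", ["g0", "g1", "g2"]))
        assert big.cell_ids <= small.cell_ids

    def test_pluripotency_gate_finds_planted_stem_cells(self, tiny_counts):
        cm, subpop = tiny_counts
        zm = zscore(cm, mode="cross_stage")
        res = gate_coexpression(zm, GeneModule.named("pluripotency"))
        stem = set(subpop[subpop == "stem"].index)
        tp = len(res.cell_ids & stem)
        assert tp / max(len(res.cell_ids), 1) >= 0.9   # precision
        assert tp / len(stem) >= 0.9                   # recall

    def test_per_stage_tallies_sum_to_gate(self, tiny_counts):
        cm, _ = tiny_counts
        zm = zscore(cm, mode="cross_stage")
        res = gate_coexpression(zm, GeneModule.named("pan_ecto"))
        assert res.per_stage["n_pass"].sum() == len(res.cell_ids)


class TestAnnotate:
    def _assignment(self):
        zm = zscore(_matrix(np.random.default_rng(2).poisson(5, (4, 12))))
        return hierarchical_cluster(zm, 3)

    def test_annotation_preserves_order_and_membership(self):
        asg = self._assignment()
        labels = {c: f"group {c}" for c in asg.cluster_ids}
        out = annotate_clusters(asg, labels)
        assert out.assignment.equals(asg.assignment)
        assert np.array_equal(out.leaf_order, asg.leaf_order)

    def test_missing_label_names_cluster(self):
        asg = self._assignment()
        labels = {c: "x" for c in asg.cluster_ids[:-1]}
        missing = asg.cluster_ids[-1]
        with pytest.raises(ValidationError, match=str(missing)):
            annotate_clusters(asg, labels)

    def test_unknown_cluster_rejected(self):
        asg = self._assignment()
        labels = {c: "x" for c in asg.cluster_ids}
        labels[99] = "ghost"
        with pytest.raises(ValidationError, match="99"):
            annotate_clusters(asg, labels)

    def test_json_round_trip(self):
        asg = self._assignment()
        labels = {c: f"group {c}" for c in asg.cluster_ids}
        colors = {c: (0.1 * c, 0.2, 0.3) for c in asg.cluster_ids}
        annotated = annotate_clusters(asg, labels, colors)
        back = annotations_from_json(asg, annotations_to_json(annotated))
        assert back.annotations == annotated.annotations
        assert back.colors == annotated.colors


def test_heatmap_written_in_leaf_order(tmp_path):
    from scmst.clustermap import plot_heatmap

    zm = zscore(_matrix(np.random.default_rng(3).poisson(6, (5, 20))))
    asg = hierarchical_cluster(zm, 3)
    fig = plot_heatmap(zm, asg, tmp_path / "hm.png")
    assert (tmp_path / "hm.png").stat().st_size > 0
    # the image x-axis follows the dendrogram leaf order
    assert fig.axes[1].get_images()[0].get_array().shape[1] == 20


def test_named_modules_match_panel_vocabulary():
    assert GENE_MODULES["pluripotency"] == ["PouV", "Nanog", "Klf4"]
    assert set(GENE_MODULES["pluripotency"]) < set(GENE_MODULES["pan_ecto"])
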