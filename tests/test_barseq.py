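import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from projcensus.barseq import (
    BarcodeDataset,
    annotate_major_classes,
    binarize,
    cluster_homogeneity,
    conditional_projection_prob,
    entropy_split,
    major_class_clustering,
    merge_by_laminae,
    normalize_barcodes,
    sublayer_enrichment,
)
from projcensus.synth import (
    BarcodeConfig,
    SubgroupDef,
    SyntheticConfig,
    generate_barcoded_neurons,
)


def make_dataset(counts, spikein=None, depths=None, brains=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"n{i}" for i in range(len(counts))]
    n = len(counts)
    return BarcodeDataset(
        counts=counts,
        spikein=pd.Series(spikein if spikein is not None else np.ones(n), index=counts.index),
        soma_depth=pd.Series(depths if depths is not None else np.full(n, 100.0), index=counts.index),
        brain_id=pd.Series(brains if brains is not None else ["b1"] * n, index=counts.index),
    )


class TestNormalizeBarcodes:
    def test_single_brain_is_spikein_division_only(self):
        data = make_dataset([[4, 0], [2, 6]], spikein=[2.0, 2.0])
        norm = normalize_barcodes(data)
        np.testing.assert_allclose(norm.values.to_numpy(), [[2, 0], [1, 3]])
        assert (norm.scale_factors.to_numpy() == 1).all()

    def test_cross_brain_scale_factor_half(self):
        # nonzero-neuron means: brain1 -> 2, brain2 -> 4  =>  brain2 scaled x0.5
        data = make_dataset(
            [[2, 0], [2, 0], [4, 0], [4, 0]],
            spikein=[1.0] * 4,
            brains=["b1", "b1", "b2", "b2"],
        )
        norm = normalize_barcodes(data)
        assert norm.scale_factors.loc["b2", 0] == pytest.approx(0.5)
        assert norm.values.iloc[2, 0] == pytest.approx(2.0)

    def test_area_empty_in_one_brain_factor_one(self):
        data = make_dataset(
            [[2, 3], [0, 3]], spikein=[1.0, 1.0], brains=["b1", "b2"]
        )
        with pytest.warns(UserWarning, match="scale factor left at 1"):
            norm = normalize_barcodes(data)
        assert norm.scale_factors.loc["b2", 0] == 1.0

    def test_zero_spikein_neuron_dropped(self):
        data = make_dataset([[1, 1], [2, 2]], spikein=[0.0, 1.0])
        with pytest.warns(UserWarning, match="zero spike-in"):
            norm = normalize_barcodes(data)
        assert len(norm.values) == 1

    def test_nonzero_means_equal_across_brains(self, config):
        dataset, _ = generate_barcoded_neurons(config)
        norm = normalize_barcodes(dataset)
        raw_nonzero = dataset.counts.loc[norm.values.index] > 0
        for area in dataset.areas:
            means = []
            for brain in norm.brain_id.unique():
                sel = (norm.brain_id == brain) & raw_nonzero[area]
                if sel.any():
                    means.append(norm.values.loc[sel, area].mean())
            if len(means) >= 2:
                assert np.ptp(means) < 1e-9

    def test_log_values_are_log1p(self):
        data = make_dataset([[4, 0], [2, 6]], spikein=[2.0, 2.0])
        norm = normalize_barcodes(data)
        np.testing.assert_allclose(norm.log_values, np.log1p(norm.values))


class TestMajorClassClustering:
    def _four_class_dataset(self, n_per=40, noise_rng=None):
        # areas: 0-1 cortex, 2 striatum, 3 thalamus, 4-5 brainstem
        archetypes = {
            "CT": [0, 0, 0, 60, 0, 0],
            "L5 ET": [5, 0, 10, 10, 50, 50],
            "IT Str+": [40, 30, 40, 0, 0, 0],
            "IT Str-": [40, 30, 0, 0, 0, 0],
        }
        rows, truth = [], []
        for name, base in archetypes.items():
            for _ in range(n_per):
                row = np.array(base, dtype=float)
                if noise_rng is not None:
                    row = noise_rng.poisson(np.maximum(row, 0.0))
                rows.append(row)
                truth.append(name)
        return make_dataset(rows), truth

    def test_noiseless_archetypes_exact_recovery(self):
        data, truth = self._four_class_dataset()
        norm = normalize_barcodes(data)
        labels = major_class_clustering(norm, n_classes=4, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_poisson_noise_recovery_ari(self):
        scores = []
        for seed in range(5):
            data, truth = self._four_class_dataset(noise_rng=np.random.default_rng(seed))
            norm = normalize_barcodes(data)
            labels = major_class_clustering(norm, n_classes=4, seed=0)
            scores.append(adjusted_rand_score(truth, labels))
        assert np.mean(scores) >= 0.95

    def test_class_annotation_names(self):
        data, truth = self._four_class_dataset()
        norm = normalize_barcodes(data)
        labels = major_class_clustering(norm, n_classes=4, seed=0)
        names = annotate_major_classes(
            labels,
            norm,
            area_roles={"thalamus": [3], "brainstem": [4, 5], "striatum": [2]},
        )
        named = labels.map(names)
        assert set(names.values()) == {"CT", "L5 ET", "IT Str+", "IT Str-"}
        assert adjusted_rand_score(truth, named) == 1.0
        # the named mapping actually matches the planted classes
        agreement = (pd.Series(truth, index=named.index) == named).mean()
        assert agreement == 1.0

    def test_fewer_than_two_classes_rejected(self):
        data, _ = self._four_class_dataset(n_per=3)
        norm = normalize_barcodes(data)
        with pytest.raises(ValueError):
            major_class_clustering(norm, n_classes=1)


class TestEntropySplit:
    def test_single_depth_bin_no_split(self):
        counts = np.zeros((30, 3), dtype=int)
        counts[:15, 0] = 5
        data = make_dataset(counts, depths=np.full(30, 110.0))
        norm = normalize_barcodes(data)
        tree = entropy_split(binarize(norm), norm.soma_depth, min_node=5, seed=0)
        assert len(tree.leaves()) == 1

    def test_disjoint_groups_delta_h_one_bit(self):
        # area-0 projectors at 200 um, non-projectors at 600 um, equal halves
        counts = np.zeros((80, 3), dtype=int)
        counts[:40, 0] = 10
        counts[:, 1] = 5  # uninformative common projection
        depths = np.array([200.0] * 40 + [600.0] * 40)
        data = make_dataset(counts, depths=depths)
        norm = normalize_barcodes(data)
        tree = entropy_split(
            binarize(norm), norm.soma_depth, min_node=10, n_perm=199, seed=0
        )
        root = tree.root
        assert root.delta_h == pytest.approx(1.0)  # mixture entropy of equal halves
        assert root.areas == (0,)
        assert len(tree.leaves()) == 2
        got = {frozenset(leaf.neuron_ids) for leaf in tree.leaves()}
        expected = {
            frozenset(f"n{i}" for i in range(40)),
            frozenset(f"n{i}" for i in range(40, 80)),
        }
        assert got == expected

    def test_accepted_splits_have_positive_delta_h(self, config):
        dataset, _ = generate_barcoded_neurons(config)
        norm = normalize_barcodes(dataset)
        tree = entropy_split(binarize(norm), norm.soma_depth, n_perm=99, seed=0)

        def check(node):
            if hasattr(node, "delta_h"):
                assert node.delta_h >= 0
                assert node.p_value < 0.05
                check(node.match)
                check(node.rest)

        check(tree.root)

    def test_max_areas_cap_respected(self):
        cfg = SyntheticConfig(seed=4)
        dataset, _ = generate_barcoded_neurons(cfg)
        norm = normalize_barcodes(dataset)
        tree = entropy_split(
            binarize(norm), norm.soma_depth, max_areas=2, n_perm=99, seed=0
        )

        def check(node):
            if hasattr(node, "areas"):
                assert len(node.areas) <= 2
                check(node.match)
                check(node.rest)

        check(tree.root)

    def test_type_i_error_controlled_quick(self):
        """Root split on depth-shuffled data accepted rarely (loose check; the
        full 400-run calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(1)
        accepts = 0
        runs = 40
        for i in range(runs):
            counts = (rng.random((60, 4)) < 0.4).astype(int) * 10
            depths = rng.uniform(0, 1200, 60)  # independent of projections
            data = make_dataset(counts, depths=depths)
            norm = normalize_barcodes(data)
            tree = entropy_split(
                binarize(norm), norm.soma_depth, n_perm=99, min_node=10, seed=100 + i
            )
            accepts += len(tree.leaves()) > 1
        assert accepts / runs <= 0.15

    def test_labels_cover_all_neurons(self, config):
        dataset, _ = generate_barcoded_neurons(config)
        norm = normalize_barcodes(dataset)
        tree = entropy_split(binarize(norm), norm.soma_depth, n_perm=99, seed=0)
        assert tree.labels.notna().all()
        assert set(tree.labels.index) == set(norm.values.index)


class TestMergeByLaminae:
    def _tree_with_two_leaves(self, depths_a, depths_b, patterns=((1, 0), (0, 1))):
        n_a, n_b = len(depths_a), len(depths_b)
        counts = np.zeros((n_a + n_b, 2), dtype=int)
        counts[:n_a] = np.array(patterns[0]) * 10
        counts[n_a:] = np.array(patterns[1]) * 10
        depths = np.concatenate([depths_a, depths_b])
        data = make_dataset(counts, depths=depths)
        norm = normalize_barcodes(data)
        tree = entropy_split(
            binarize(norm), norm.soma_depth, min_node=5, n_perm=99, seed=0
        )
        return tree, norm

    def _manual_tree(self, norm, split_at):
        """Two-leaf tree splitting the dataset at a fixed neuron index."""
        from projcensus.barseq import LeafNode, SplitNode, SubgroupTree

        ids = list(norm.values.index)
        node = SplitNode(areas=(0,), pattern=(1,), delta_h=0.5, p_value=0.01)
        node.match = LeafNode(ids[:split_at], label=1)
        node.rest = LeafNode(ids[split_at:], label=2)
        labels = pd.Series(
            [1] * split_at + [2] * (len(ids) - split_at), index=ids, name="subgroup"
        )
        return SubgroupTree(root=node, labels=labels)

    def test_similar_laminae_same_class_merged(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((60, 2), dtype=int)
        counts[:30, 0] = 10
        counts[30:, 1] = 10
        data = make_dataset(counts, depths=rng.uniform(300, 500, 60))
        norm = normalize_barcodes(data)
        tree = self._manual_tree(norm, 30)
        classes = pd.Series("IT", index=norm.values.index)
        merged = merge_by_laminae(tree, norm, classes)
        assert merged.nunique() == 1  # indistinguishable laminae: merged

    def test_median_window_rule_blocks_merge(self):
        depths_a = np.random.default_rng(0).normal(300, 10, 40).clip(0)
        depths_b = np.random.default_rng(1).normal(600, 10, 40).clip(0)
        tree, norm = self._tree_with_two_leaves(depths_a, depths_b)
        assert len(tree.leaves()) == 2
        classes = pd.Series("IT", index=norm.values.index)
        merged = merge_by_laminae(tree, norm, classes, median_window=200.0)
        assert merged.nunique() == 2  # medians 300 vs 600: window forbids merge

    def test_never_merges_across_major_classes(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((60, 2), dtype=int)
        counts[:30, 0] = 10
        counts[30:, 1] = 10
        data = make_dataset(counts, depths=rng.uniform(300, 500, 60))
        norm = normalize_barcodes(data)
        tree = self._manual_tree(norm, 30)
        classes = pd.Series(["A"] * 30 + ["B"] * 30, index=norm.values.index)
        merged = merge_by_laminae(tree, norm, classes)
        assert merged.nunique() == 2  # identical laminae but different classes

    def test_final_label_count_at_most_leaf_count(self, config):
        dataset, _ = generate_barcoded_neurons(config)
        norm = normalize_barcodes(dataset)
        tree = entropy_split(binarize(norm), norm.soma_depth, n_perm=99, seed=0)
        classes = pd.Series("IT", index=norm.values.index)
        merged = merge_by_laminae(tree, norm, classes)
        assert merged.nunique() <= len(tree.leaves())


class TestConditionalProb:
    def test_four_neuron_direct_count(self):
        binary = pd.DataFrame(
            {"x": [1, 1, 0, 1], "y": [1, 1, 1, 0]},
            index=[f"n{i}" for i in range(4)],
        ).astype(bool)
        result = conditional_projection_prob(binary, "x", "y")
        assert result["p_x_given_y1"] == pytest.approx(2 / 3)
        assert result["p_x_given_y0"] == pytest.approx(1.0)
        assert result["n_y1"] == 3 and result["n_y0"] == 1

    def test_missing_conditional_reported_nan(self):
        binary = pd.DataFrame({"x": [1, 0], "y": [1, 1]}, index=["a", "b"]).astype(bool)
        result = conditional_projection_prob(binary, "x", "y")
        assert np.isnan(result["p_x_given_y0"])
        assert np.isnan(result["delta"])

    def test_law_of_total_probability(self, rng):
        binary = pd.DataFrame(
            rng.random((200, 2)) < 0.4, columns=["x", "y"],
            index=[f"n{i}" for i in range(200)],
        )
        result = conditional_projection_prob(binary, "x", "y")
        p_y1 = binary["y"].mean()
        reconstructed = (
            result["p_x_given_y1"] * p_y1 + result["p_x_given_y0"] * (1 - p_y1)
        )
        assert reconstructed == pytest.approx(binary["x"].mean(), abs=1e-12)

    def test_independent_projections_delta_near_zero(self):
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            binary = pd.DataFrame(
                rng.random((500, 2)) < 0.5, columns=["x", "y"],
                index=range(500),
            )
            deltas.append(conditional_projection_prob(binary, "x", "y")["delta"])
        # each delta ~ N(0, ~0.045); all within 4 sigma
        assert np.max(np.abs(deltas)) < 0.18

    def test_empty_stratum_rejected(self):
        binary = pd.DataFrame({"x": [1], "y": [0]}, index=["a"]).astype(bool)
        with pytest.raises(ValueError, match="empty"):
            conditional_projection_prob(binary, "x", "y", stratum=[])


class TestSublayerEnrichment:
    def test_single_subgroup_enrichment_one(self):
        labels = pd.Series([1] * 10, index=range(10))
        sublayer = pd.Series(["L2"] * 5 + ["L5"] * 5, index=range(10))
        result = sublayer_enrichment(labels, sublayer)
        np.testing.assert_allclose(result["enrichment"], 1.0)
        assert (result["rank"] == 1).all()

    def test_confined_subgroup(self):
        labels = pd.Series([1] * 5 + [2] * 15, index=range(20))
        sublayer = pd.Series(["L2"] * 5 + ["L5"] * 15, index=range(20))
        result = sublayer_enrichment(labels, sublayer).set_index(["sublayer", "subgroup"])
        # subgroup 1 overall fraction 0.25; within L2 it is 1.0 -> enrichment 4
        assert result.loc[("L2", 1), "enrichment"] == pytest.approx(4.0)
        assert ("L5", 1) not in result.index  # zero enrichment not in top list

    def test_planted_design_top_pairs_unique(self):
        # 6 sublayers, 4 subgroups arranged so each sublayer's top-2 pair differs
        rng = np.random.default_rng(0)
        assignments = {
            "S1": [1, 2], "S2": [2, 3], "S3": [3, 4],
            "S4": [4, 1], "S5": [1, 3], "S6": [2, 4],
        }
        labels, sublayers, idx = [], [], []
        i = 0
        for sl, (major, minor) in assignments.items():
            for _ in range(30):
                labels.append(major if rng.random() < 0.7 else minor)
                sublayers.append(sl)
                idx.append(i)
                i += 1
        result = sublayer_enrichment(
            pd.Series(labels, index=idx), pd.Series(sublayers, index=idx)
        )
        pairs = result.groupby("sublayer")["subgroup"].apply(tuple)
        assert len(set(pairs)) == len(pairs)


class TestClusterHomogeneity:
    def test_identical_rows_correlation_one(self):
        data = make_dataset([[3, 1, 0]] * 20)
        norm = normalize_barcodes(data)
        labels = pd.Series([1] * 20, index=norm.values.index)
        result = cluster_homogeneity(norm, labels, sizes=[2, 5], n_boot=50, seed=0)
        np.testing.assert_allclose(result["correlation"], 1.0)

    def test_median_correlation_non_decreasing(self, config):
        dataset, _ = generate_barcoded_neurons(config)
        norm = normalize_barcodes(dataset)
        labels = pd.Series(1, index=norm.values.index)
        result = cluster_homogeneity(
            norm, labels, sizes=[3, 10, 30, 100], n_boot=200, seed=0
        )
        medians = result.groupby("size")["correlation"].median()
        assert (medians.diff().dropna() >= -0.02).all()

    def test_boot_count_respected(self):
        data = make_dataset([[3, 1, 0]] * 10)
        norm = normalize_barcodes(data)
        labels = pd.Series([1] * 10, index=norm.values.index)
        result = cluster_homogeneity(norm, labels, sizes=[4], n_boot=17, seed=0)
        assert len(result) == 17
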