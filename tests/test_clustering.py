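"""Feature normalization, correlation k-means, classes, coherence, tSNE."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

import motilikit as mk
from motilikit.aprw import PARAMETER_NAMES
from motilikit.clustering import (
    assign_clusters,
    correlation_distance,
    denormalize,
)
from conftest import planted_parameter_table


class TestNormalizeFeatures:
    def test_training_matrix_is_zero_mean_unit_sd(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        np.testing.assert_allclose(fm.array().mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(fm.array().std(axis=0), 1.0, atol=1e-9)

    def test_round_trip_inverts_transform(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        back = denormalize(fm)
        orig = table.set_index(["condition_id", "cell_id"])[PARAMETER_NAMES]
        np.testing.assert_allclose(back.to_numpy(), orig.to_numpy(),
                                   rtol=1e-9)

    def test_stored_stats_reproduce_training_matrix(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        again = mk.normalize_features(table, stats=fm.stats)
        np.testing.assert_allclose(again.array(), fm.array())

    def test_degenerate_column_raises(self):
        rows = [dict(zip(PARAMETER_NAMES, [1.0 + i, 2, 3, 2, 1, 4, 2, 2]))
                for i in range(5)]
        table = pd.DataFrame(rows)  # all columns but the first constant
        with pytest.raises(ValueError, match="distinct"):
            mk.normalize_features(table)

    def test_nonpositive_cells_excluded_and_counted(self, planted_params):
        table, _ = planted_params
        table = table.copy()
        table.loc[table.index[:7], "Dp"] = -1.0
        fm = mk.normalize_features(table)
        assert fm.excluded == 7
        assert len(fm) == len(table) - 7


class TestKMeansCorrelation:
    def test_two_archetypes_fully_recovered(self):
        table, truth = planted_parameter_table(n_per=200, seed=1)
        two = table[np.isin(truth, ["a", "d"])]
        fm = mk.normalize_features(two)
        model = mk.kmeans_correlation(fm, k=2, replicates=10, seed=0)
        ari = adjusted_rand_score(
            fm.values.index.get_level_values("condition_id"),
            model.assignments,
        )
        assert ari == 1.0

    def test_four_archetypes_ari(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=10, seed=0)
        ari = adjusted_rand_score(
            fm.values.index.get_level_values("condition_id"),
            model.assignments,
        )
        assert ari >= 0.9

    def test_k_one_single_cluster(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=1, replicates=2, seed=0)
        assert model.assignments.nunique() == 1
        np.testing.assert_allclose(model.centroids[0],
                                   fm.array().mean(axis=0), atol=1e-12)

    def test_row_permutation_invariance(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model_a = mk.kmeans_correlation(fm, k=4, replicates=10, seed=0)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(table))
        fm_b = mk.normalize_features(table.iloc[perm])
        model_b = mk.kmeans_correlation(fm_b, k=4, replicates=10, seed=0)
        joined = model_a.assignments.rename("a").to_frame().join(
            model_b.assignments.rename("b")
        )
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_excessive_k_raises(self):
        table, _ = planted_parameter_table(n_per=3, seed=2)
        fm = mk.normalize_features(table)
        with pytest.raises(ValueError, match="distinct"):
            mk.kmeans_correlation(fm, k=13, replicates=1)

    def test_frozen_assignment_matches_training_labels(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        np.testing.assert_array_equal(
            assign_clusters(model, fm.array()),
            model.assignments.to_numpy(),
        )


class TestSelectK:
    def test_silhouette_peaks_at_planted_k(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        diag = mk.select_k(fm, k_range=[2, 3, 4, 5, 6], replicates=5)
        best = diag.loc[diag["silhouette"].idxmax(), "k"]
        assert best == 4

    def test_inertia_nonincreasing(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        diag = mk.select_k(fm, k_range=[2, 4, 8, 12], replicates=5)
        assert (np.diff(diag["inertia"]) <= 1e-6).all()


class TestCoherence:
    def test_matrix_equals_brute_force(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        coh = mk.coherence_matrix(fm, model)
        oracle = cdist(fm.array(), model.centroids)
        np.testing.assert_allclose(coh.to_numpy(), oracle)

    def test_staircase_property(self, planted_params):
        # within-cluster distance is the row minimum for almost every cell
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        coh = mk.coherence_matrix(fm, model).to_numpy()
        own = coh[np.arange(len(coh)), model.assignments.to_numpy()]
        assert (own == coh.min(axis=1)).mean() >= 0.99

    def test_cell_at_centroid_has_zero_distance(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        d = cdist(model.centroids[:1], model.centroids)[0]
        assert d[0] == 0.0


class TestBehaviorClasses:
    def test_class_map_is_partition_of_clusters(self, short_study):
        model = short_study["model"]
        assert set(model.class_map) == set(range(model.k))
        assert len(model.class_labels) == 4

    def test_classes_ordered_by_msd100(self, short_study):
        model = short_study["model"]
        col = model.stats.columns.index("MSD100")
        means = {}
        for cls in model.class_labels:
            members = [j for j, c in model.class_map.items() if c == cls]
            means[cls] = model.centroids[members, col].mean()
        ordered = sorted(means, key=means.get)
        assert ordered == model.class_labels  # SG1 least motile ... SG4 most

    def test_two_tight_pairs_grouped(self):
        table, _ = planted_parameter_table(n_per=100, seed=3)
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=10, seed=0)
        model = mk.derive_behavior_classes(model, n_classes=2)
        assert len(set(model.class_map.values())) == 2

    def test_cutting_at_k_gives_singletons(self):
        table, _ = planted_parameter_table(n_per=100, seed=3)
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=10, seed=0)
        model = mk.derive_behavior_classes(model, n_classes=4)
        assert len(set(model.class_map.values())) == 4

    def test_n_classes_exceeding_k_raises(self):
        table, _ = planted_parameter_table(n_per=50, seed=3)
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=3, replicates=5, seed=0)
        with pytest.raises(ValueError):
            mk.derive_behavior_classes(model, n_classes=5)


class TestAbundanceProfiles:
    def test_profiles_sum_to_one(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        model = mk.derive_behavior_classes(model)
        clusters, classes = mk.abundance_profiles(model)
        np.testing.assert_allclose(clusters.sum(axis=1), 1.0)
        np.testing.assert_allclose(classes.sum(axis=1), 1.0)

    def test_equals_brute_force_tabulation(self, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        clusters, _ = mk.abundance_profiles(model)
        assign = model.assignments
        conds = assign.index.get_level_values("condition_id")
        for cond in clusters.index:
            sub = assign[conds == cond]
            for j in range(model.k):
                expected = (sub == j).sum() / len(sub)
                assert clusters.loc[cond].iloc[j] == pytest.approx(expected)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, planted_params):
        table, _ = planted_params
        fm = mk.normalize_features(table)
        model = mk.kmeans_correlation(fm, k=4, replicates=5, seed=0)
        model = mk.derive_behavior_classes(model)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = mk.clustering.ClusterModel.from_json(path)
        np.testing.assert_allclose(back.centroids, model.centroids)
        assert back.class_map == model.class_map
        np.testing.assert_array_equal(
            assign_clusters(back, fm.array()),
            model.assignments.to_numpy(),
        )


class TestTSNE:
    def test_same_seed_identical_embedding(self):
        table, _ = planted_parameter_table(n_per=60, seed=5)
        fm = mk.normalize_features(table)
        a = mk.embed_tsne(fm, seed=1, perplexity=15)
        b = mk.embed_tsne(fm, seed=1, perplexity=15)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_too_few_cells_raise(self):
        table, _ = planted_parameter_table(n_per=10, seed=5)
        fm = mk.normalize_features(table)
        with pytest.raises(ValueError, match="perplexity"):
            mk.embed_tsne(fm, seed=1, perplexity=30)


def test_correlation_distance_helper_matches_scipy(rng):
    from scipy.spatial.distance import cdist as scipy_cdist

    a = rng.normal(size=(10, 8))
    b = rng.normal(size=(6, 8))
    np.testing.assert_allclose(
        correlation_distance(a, b),
        scipy_cdist(a, b, metric="correlation"),
        atol=1e-12,
    )
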