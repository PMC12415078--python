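"""K-means clustering, cluster-count selection, silhouette, discard logic."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mechanospec.clustering import (centroid_difference,
                                    discard_offtarget_cluster, kmeans_cluster,
                                    select_cluster_count, silhouette_profile,
                                    spectra_matrix)
from mechanospec.pipeline import prep_raman_map
from mechanospec.synthetic import (GLYCOGEN_BANDS, generate_phantom_map,
                                   organoid_line_config, u87_line_config)


def _silhouette_brute(x, labels):
    """Loop-based silhouette oracle: s(i) = (b - a) / max(a, b)."""
    n = x.shape[0]
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(np.mean([np.linalg.norm(x[i] - x[j])
                         for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


class TestKMeans:
    def test_noiseless_phantom_recovered_exactly(self):
        cfg = u87_line_config(seed=5, raman_noise_sd=0.0)
        maps = [generate_phantom_map(cfg)]
        prepped = prep_raman_map([s for m in maps for s in m.raman])
        mat, _ = spectra_matrix(prepped)
        truth = [lab for m in maps for lab in m.labels]
        model = kmeans_cluster(mat, k=3, seed=0)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_identical_spectra_flag_degenerate(self):
        mat = np.tile(np.linspace(0, 1, 30), (10, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            model = kmeans_cluster(mat, k=2, seed=0)
        assert model.degenerate

    def test_duplicated_pair_splits_perfectly(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(5, 1, 40)
        mat = np.vstack([np.tile(a, (50, 1)), np.tile(b, (50, 1))])
        model = kmeans_cluster(mat, k=2, seed=0)
        assert model.wcss == pytest.approx(0.0, abs=1e-18)
        assert len(set(model.labels[:50])) == 1
        assert len(set(model.labels[50:])) == 1

    def test_fixed_seed_reproduces_labels(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        m1 = kmeans_cluster(mat, 3, seed=11)
        m2 = kmeans_cluster(mat, 3, seed=11)
        assert np.array_equal(m1.labels, m2.labels)

    def test_clusters_numbered_by_descending_size(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        model = kmeans_cluster(mat, 3, seed=0)
        sizes = model.cluster_sizes()
        assert np.all(np.diff(sizes) <= 0)

    def test_invalid_k_rejected(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        with pytest.raises(ValueError):
            kmeans_cluster(mat, 1, seed=0)
        with pytest.raises(ValueError):
            kmeans_cluster(mat, mat.shape[0] + 1, seed=0)


class TestSelection:
    def test_vote_is_consistent_with_criterion_table(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        k_opt, table = select_cluster_count(mat, range(2, 7), seed=0)
        votes = [table["silhouette"].idxmax(),
                 table["davies_bouldin"].idxmin(),
                 table["calinski_harabasz"].idxmax()]
        counts = {k: votes.count(k) for k in set(votes)}
        best = max(counts.values())
        assert k_opt == min(k for k, c in counts.items() if c == best)

    def test_ground_truth_class_recovery_with_low_noise(self):
        """With noise below 5 % of the strongest band, k-means reassigns
        >= 99 % of points to their generating class."""
        maps = [generate_phantom_map(u87_line_config(seed=700 + i,
                                                     raman_noise_sd=0.05))
                for i in range(3)]
        prepped = prep_raman_map([s for m in maps for s in m.raman])
        mat, _ = spectra_matrix(prepped)
        truth = np.array([lab for m in maps for lab in m.labels])
        model = kmeans_cluster(mat, k=3, seed=0)
        # best label <-> class matching
        correct = 0
        for c in range(3):
            names, cnt = np.unique(truth[model.labels == c],
                                   return_counts=True)
            correct += cnt.max()
        assert correct / truth.size >= 0.99

    def test_empty_k_range_rejected(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        with pytest.raises(ValueError):
            select_cluster_count(mat, [], seed=0)


class TestSilhouette:
    def test_matches_brute_force_on_toy(self, rng):
        x = np.vstack([rng.normal(0, 0.05, (5, 3)),
                       rng.normal(3, 0.05, (5, 3))])
        model = kmeans_cluster(x, 2, seed=0)
        values, per_cluster = silhouette_profile(model, x)
        brute = _silhouette_brute(x, model.labels)
        assert np.allclose(values, brute, atol=1e-12)
        assert values.mean() > 0.9

    def test_split_single_class_scores_near_zero(self, rng):
        x = rng.normal(0, 1.0, (40, 3))
        model = kmeans_cluster(x, 2, seed=0)
        values, _ = silhouette_profile(model, x)
        assert abs(values.mean()) < 0.45

    def test_two_singletons_are_zero_by_convention(self, rng):
        x = rng.normal(0, 1, (2, 4))
        model = kmeans_cluster(x, 2, seed=0)
        values, per_cluster = silhouette_profile(model, x)
        assert np.all(values == 0.0)


class TestCentroids:
    def test_difference_antisymmetric_and_zero_on_self(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        model = kmeans_cluster(mat, 3, seed=0)
        d01 = centroid_difference(model, 0, 1)
        assert np.allclose(d01, -centroid_difference(model, 1, 0))
        assert np.allclose(centroid_difference(model, 2, 2), 0.0)

    def test_glycogen_signature_in_centroid_difference(self, u87_small_dataset):
        """protein+glycogen centroid minus cytoplasm centroid matches a pure
        glycogen reference spectrum (cosine similarity > 0.9)."""
        maps, mat, axis, truth = u87_small_dataset
        model = kmeans_cluster(mat, 3, seed=0)
        truth = np.array(truth)

        def cluster_for(name):
            overlaps = [np.sum(truth[model.labels == c] == name)
                        for c in range(3)]
            return int(np.argmax(overlaps))

        diff = centroid_difference(model, cluster_for("protein_glycogen"),
                                   cluster_for("cytoplasm"))
        from mechanospec.brillouin import lorentzian
        ref = np.zeros_like(axis)
        for c, w, a in GLYCOGEN_BANDS:
            ref += lorentzian(axis, c, w, a)
        cos = np.dot(diff, ref) / (np.linalg.norm(diff) * np.linalg.norm(ref))
        assert cos > 0.9


@pytest.fixture(scope="module")
def organoid_model():
    maps = [generate_phantom_map(organoid_line_config(seed=500 + i))
            for i in range(8)]
    prepped = prep_raman_map([s for m in maps for s in m.raman])
    mat, _ = spectra_matrix(prepped)
    truth = np.array([lab for m in maps for lab in m.labels])
    model = kmeans_cluster(mat, 6, seed=0)
    return model, truth


class TestDiscard:
    def test_medium_cluster_discarded_five_retained(self, organoid_model):
        model, truth = organoid_model
        labels, n_disc, discarded = discard_offtarget_cluster(model)
        assert len(discarded) == 1
        assert len(set(labels[labels >= 0])) == 5
        assert np.all(truth[labels == -1] == "medium")

    def test_no_medium_means_nothing_discarded(self, u87_small_dataset):
        _, mat, _, _ = u87_small_dataset
        model = kmeans_cluster(mat, 3, seed=0)
        labels, n_disc, discarded = discard_offtarget_cluster(model)
        assert n_disc == 0 and discarded == []

    def test_vacuous_criteria_discard_nothing(self, organoid_model):
        model, _ = organoid_model
        labels, n_disc, discarded = discard_offtarget_cluster(
            model, cosine_threshold=1.1, prominence_floor=0.0)
        assert n_disc == 0 and discarded == []

    def test_all_discarded_is_an_error(self, organoid_model):
        model, _ = organoid_model
        with pytest.raises(ValueError, match="all clusters"):
            discard_offtarget_cluster(model, prominence_floor=np.inf)
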