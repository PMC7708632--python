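"""Hi-C matrix operations: KR balancing closed forms, O/E, Pearson maps,
compartment eigenvector recovery, histone clusters, contact ratios, APA,
and replication timing."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nucarch.compartments import (
    ClusterAssignment,
    ContactMatrix,
    TrackSet,
    apa,
    cluster_contact_log2ratio,
    compartment_eigenvector,
    kmeans_histone_clusters,
    kr_balance,
    oe_transform,
    pearson_map,
    replication_timing,
    timing_preservation,
)
from nucarch.simulate_genome import MARK_NAMES, GenomeSpec, default_cluster_archetypes, generate_contact_data


class TestKrBalance:
    def test_closed_form_rank_one(self):
        m = ContactMatrix(np.array([[1.0, 2.0], [2.0, 4.0]]), 1000)
        out = kr_balance(m)
        assert np.allclose(out.scaling, [1 / np.sqrt(2), 1 / (2 * np.sqrt(2))], atol=1e-6)
        assert np.allclose(out.matrix.sum(axis=1), 1.0, atol=1e-6)

    def test_already_balanced_fixed_point(self):
        # a doubly stochastic matrix needs only a constant scaling vector
        m = ContactMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]), 1000)
        out = kr_balance(m)
        assert np.allclose(out.scaling, out.scaling[0], atol=1e-5)
        assert np.allclose(out.matrix, m.matrix, rtol=1e-5)

    def test_rowsum_postcondition(self):
        pre, _, _, _, _ = generate_contact_data(GenomeSpec(sampling_depth=1.0, seed=1))
        out = kr_balance(pre, tol=1e-6)
        keep = ~out.masked_bins
        assert np.abs(out.matrix.sum(axis=1)[keep] - 1.0).max() < 1e-6

    def test_masked_zero_rows_stay_zero(self):
        mat = np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0], [0.0, 0.0, 0.0]])
        out = kr_balance(ContactMatrix(mat, 1000))
        assert np.all(out.matrix[2] == 0) and out.scaling[2] == 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), 1000)


class TestOeAndPearson:
    def test_constant_matrix_oe_is_one(self):
        m = ContactMatrix(np.full((6, 6), 7.0), 1000)
        assert np.allclose(oe_transform(m), 1.0)

    def test_oe_idempotent(self):
        pre, _, _, _, _ = generate_contact_data(GenomeSpec(n_bins=60, seed=2))
        oe1 = oe_transform(kr_balance(pre))
        oe2 = oe_transform(ContactMatrix(np.nan_to_num(oe1), 1000))
        finite = np.isfinite(oe1) & np.isfinite(oe2)
        assert np.allclose(oe1[finite], oe2[finite], rtol=1e-9)

    def test_pearson_identical_and_negated_rows(self):
        # rows 0 and 3 are identical (correlation 1); row 2 is the negation
        # of row 0 up to its mean structure, checked via the map sign
        oe = np.array([
            [1.0, 0.9, -0.9, 1.0, 0.9, -0.9],
            [0.9, 1.0, -0.8, 0.9, 1.0, -0.8],
            [-0.9, -0.8, 1.0, -0.9, -0.8, 1.0],
            [1.0, 0.9, -0.9, 1.0, 0.9, -0.9],
            [0.9, 1.0, -0.8, 0.9, 1.0, -0.8],
            [-0.9, -0.8, 1.0, -0.9, -0.8, 1.0],
        ])
        pm = pearson_map(oe)
        assert pm[0, 3] == pytest.approx(1.0)  # identical rows
        assert np.allclose(np.diag(pm), 1.0)
        assert np.corrcoef(oe[0], -oe[0])[0, 1] == pytest.approx(-1.0)
        assert pm[0, 2] < 0  # anti-correlated rows get negative entries

    def test_plaid_sign_structure(self):
        spec = GenomeSpec(n_bins=60, compartment_block=10, seed=3)
        pre, _, _, _, truth = generate_contact_data(spec)
        pm = pearson_map(oe_transform(kr_balance(pre)))
        same = np.equal.outer(truth.compartment_sign, truth.compartment_sign)
        off = ~np.eye(60, dtype=bool)
        assert pm[same & off].mean() > pm[~same].mean()


class TestEigenvector:
    def test_checkerboard_sign_recovery_exact(self):
        spec = GenomeSpec(n_bins=60, compartment_block=10, seed=4)
        pre, _, _, _, truth = generate_contact_data(spec)  # noiseless expected counts
        ev = compartment_eigenvector(pearson_map(oe_transform(kr_balance(pre))), reference=truth.early)
        assert np.array_equal(np.sign(ev), truth.compartment_sign)

    def test_orientation_rule(self):
        spec = GenomeSpec(n_bins=60, seed=5)
        pre, _, _, _, truth = generate_contact_data(spec)
        pm = pearson_map(oe_transform(kr_balance(pre)))
        ev = compartment_eigenvector(pm, reference=None)
        ev_ref = compartment_eigenvector(pm, reference=ev)
        assert np.corrcoef(ev, ev_ref)[0, 1] > 0

    def test_permutation_equivariance(self):
        spec = GenomeSpec(n_bins=60, seed=6)
        pre, _, _, _, truth = generate_contact_data(spec)
        pm = pearson_map(oe_transform(kr_balance(pre)))
        ev = compartment_eigenvector(pm, reference=truth.early)
        perm = np.random.default_rng(0).permutation(60)
        ev_p = compartment_eigenvector(pm[np.ix_(perm, perm)], reference=truth.early[perm])
        assert np.allclose(np.abs(ev_p), np.abs(ev[perm]), atol=1e-9)

    def test_degenerate_leading_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compartment_eigenvector(np.eye(10))


class TestHistoneClusters:
    def test_zscore_normalisation(self):
        spec = GenomeSpec(seed=7)
        _, _, tracks, _, _ = generate_contact_data(spec)
        X = tracks.values(list(MARK_NAMES))
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_two_separable_archetypes_perfect_partition(self, rng):
        arch = np.vstack([np.full(9, 3.0), np.full(9, -3.0)])
        labels_true = rng.integers(0, 2, 80)
        X = arch[labels_true]  # no noise
        ts = TrackSet(pd.DataFrame(X, columns=list(MARK_NAMES)), 25_000)
        ca = kmeans_histone_clusters(ts, k=2, seed=0)
        assert adjusted_rand_score(labels_true, ca.labels) == 1.0

    def test_six_clusters_recovered_at_low_noise(self):
        spec = GenomeSpec(track_noise_sd=0.3, seed=8)
        _, _, tracks, _, truth = generate_contact_data(spec)
        marks_only = TrackSet(tracks.tracks[list(MARK_NAMES)], spec.resolution)
        ca = kmeans_histone_clusters(marks_only, k=6, seed=0)
        assert adjusted_rand_score(truth.cluster_labels, ca.labels) >= 0.95

    def test_relabelled_by_descending_size(self):
        spec = GenomeSpec(seed=9)
        _, _, tracks, _, _ = generate_contact_data(spec)
        ca = kmeans_histone_clusters(TrackSet(tracks.tracks[list(MARK_NAMES)], spec.resolution), k=6, seed=0)
        assert np.all(np.diff(ca.sizes) <= 0)

    def test_k_exceeding_bins_rejected(self):
        ts = TrackSet(pd.DataFrame(np.random.default_rng(0).normal(size=(4, 9)), columns=list(MARK_NAMES)), 25_000)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_histone_clusters(ts, k=6)


class TestClusterContacts:
    def test_equal_matrices_zero_ratio(self):
        pre, _, _, _, truth = generate_contact_data(GenomeSpec(seed=10))
        ca = ClusterAssignment(truth.cluster_labels, 6)
        lr = cluster_contact_log2ratio(pre, pre, ca)
        assert np.allclose(lr[np.isfinite(lr)], 0.0)

    def test_noiseless_doubling_gives_exactly_one(self):
        spec = GenomeSpec(strengthen_factor=2.0, seed=11)  # exact expected counts
        pre, post, _, _, truth = generate_contact_data(spec)
        ca = ClusterAssignment(truth.cluster_labels, 6)
        lr = cluster_contact_log2ratio(post, pre, ca)
        c = truth.strengthen_cluster - 1
        assert lr[c, c] == pytest.approx(1.0, abs=1e-12)
        off = np.ones((6, 6), dtype=bool)
        off[c, c] = False
        assert np.allclose(lr[off], 0.0, atol=1e-12)

    def test_strengthened_cluster_maximal_under_noise(self):
        spec = GenomeSpec(strengthen_factor=2.0, sampling_depth=1.0, seed=12)
        pre, post, tracks, _, truth = generate_contact_data(spec)
        ca = kmeans_histone_clusters(TrackSet(tracks.tracks[list(MARK_NAMES)], spec.resolution), k=6, seed=0)
        lr = cluster_contact_log2ratio(kr_balance(post), kr_balance(pre), ca)
        c_new = ca.labels[truth.cluster_labels == truth.strengthen_cluster]
        c = int(np.bincount(c_new).argmax()) - 1
        assert np.nanargmax(lr) == c * 6 + c

    def test_antisymmetric_under_swap(self):
        pre, post, _, _, truth = generate_contact_data(GenomeSpec(sampling_depth=1.0, seed=13))
        ca = ClusterAssignment(truth.cluster_labels, 6)
        a = cluster_contact_log2ratio(post, pre, ca)
        b = cluster_contact_log2ratio(pre, post, ca)
        f = np.isfinite(a)
        assert np.allclose(a[f], -b[f])


class TestApa:
    def test_planted_peaks_enriched(self):
        pre, _, _, loops, _ = generate_contact_data(GenomeSpec(seed=14))
        _, _, ratio, used = apa(pre, loops, window=10)
        assert ratio > 1.0 and used == len(loops)

    def test_uniform_matrix_ratio_one(self):
        m = ContactMatrix(np.full((80, 80), 5.0), 1000)
        _, _, ratio, _ = apa(m, [(20, 50), (15, 60)], window=10)
        assert ratio == pytest.approx(1.0)

    def test_shuffled_loops_lose_enrichment(self, rng):
        pre, _, _, loops, _ = generate_contact_data(GenomeSpec(seed=15))
        _, _, ratio_planted, _ = apa(pre, loops, window=10)
        shuffled = [(int(i), int(i + d)) for i, d in zip(rng.integers(12, 150, 20), rng.integers(25, 60, 20)) if i + d < 188]
        _, _, ratio_shuffled, _ = apa(pre, shuffled, window=10)
        assert ratio_shuffled < ratio_planted

    def test_no_usable_loops_raises(self):
        m = ContactMatrix(np.full((30, 30), 5.0), 1000)
        with pytest.raises(ValueError, match="no usable loops"):
            apa(m, [(0, 5)], window=10)


class TestReplicationTiming:
    def test_equal_tracks_zero_log_ratio(self):
        t = replication_timing(np.full(50, 10.0), np.full(50, 10.0))
        assert np.allclose(t.log2_ratio, 0.0)

    def test_monotone_track_percentiles_are_scaled_ranks(self):
        e = np.arange(1.0, 21.0)
        t = replication_timing(e, np.ones(20))
        assert np.allclose(t.percentile, 100 * np.arange(20) / 19)

    def test_compartments_split_timing(self):
        _, _, _, _, truth = generate_contact_data(GenomeSpec(seed=16))
        t = replication_timing(truth.early, truth.late)
        assert t.log2_ratio[truth.compartment_sign > 0].mean() > 0
        assert t.log2_ratio[truth.compartment_sign < 0].mean() < 0

    def test_identical_tracks_spearman_one(self):
        t1 = replication_timing(np.arange(1.0, 31.0), np.ones(30))
        rho, table = timing_preservation(t1, t1)
        assert rho == pytest.approx(1.0)
        assert len(table) == 30

    def test_reversed_track_spearman_minus_one(self):
        t1 = replication_timing(np.arange(1.0, 31.0), np.ones(30))
        t2 = replication_timing(np.arange(30.0, 0.0, -1.0), np.ones(30))
        rho, _ = timing_preservation(t1, t2)
        assert rho == pytest.approx(-1.0)

    def test_noisy_treated_track_high_correlation(self, rng):
        _, _, _, _, truth = generate_contact_data(GenomeSpec(seed=17))
        t1 = replication_timing(truth.early, truth.late)
        t2 = replication_timing(truth.early + rng.normal(0, 3, truth.early.size).clip(-50, 50), truth.late)
        rho, _ = timing_preservation(t1, t2)
        assert rho >= 0.95

    def test_all_zero_tracks_rejected(self):
        with pytest.raises(ValueError):
            replication_timing(np.zeros(10), np.zeros(10))
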