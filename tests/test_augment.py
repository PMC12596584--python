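import numpy as np
import pytest

from geoloci import (
    CoordinateSet,
    GenotypeMatrix,
    SpatialClustering,
    cluster_coordinates,
    interpolate_coordinates,
    mendelian_cross,
    oversample,
    stratified_split,
)
from geoloci.errors import AugmentationError, ConfigError, DegenerateGeometryError, InputError
from geoloci.evaluate import haversine_km
from geoloci.geometry import unproject_km


def _coords(xy_km, origin=(-92.0, 36.0)):
    lonlat = unproject_km(np.asarray(xy_km, float), np.asarray(origin))
    ids = np.array([f"s{i:03d}" for i in range(len(lonlat))], dtype=object)
    return CoordinateSet(ids, lonlat[:, 0], lonlat[:, 1])


def _clouds(rng, sizes, centers, spread=5.0):
    xy = np.vstack(
        [rng.normal(0, spread, (n, 2)) + c for n, c in zip(sizes, centers)]
    )
    labels = np.concatenate([[i] * n for i, n in enumerate(sizes)])
    return xy, labels


class TestClusterCoordinates:
    def test_two_separated_clouds(self, rng):
        xy, _ = _clouds(rng, (40, 40), [(0, 0), (300, 0)])
        clus = cluster_coordinates(_coords(xy), seed=0)
        assert clus.k == 2
        assert clus.mean_silhouette > 0.7

    def test_three_separated_clouds(self, rng):
        xy, _ = _clouds(rng, (30, 30, 30), [(0, 0), (300, 0), (150, 260)])
        clus = cluster_coordinates(_coords(xy), seed=0)
        assert clus.k == 3

    def test_silhouette_matches_independent_recomputation(self, ibd_features):
        from sklearn.metrics import silhouette_score

        from geoloci.geometry import project_km

        _, C = ibd_features
        clus = cluster_coordinates(C, seed=1)
        xy, _ = project_km(C.lonlat)
        assert abs(clus.mean_silhouette - silhouette_score(xy, clus.labels)) < 1e-9

    def test_identical_points_degenerate(self):
        C = _coords(np.zeros((10, 2)))
        with pytest.raises(DegenerateGeometryError):
            cluster_coordinates(C)


class TestMendelianCross:
    def test_homozygous_parents_forced_outcomes(self, rng):
        zero = np.zeros(50, dtype=np.int8)
        two = np.full(50, 2, dtype=np.int8)
        assert (mendelian_cross(zero, zero, rng) == 0).all()
        assert (mendelian_cross(zero, two, rng) == 1).all()
        assert (mendelian_cross(two, two, rng) == 2).all()

    def test_het_cross_segregation_ratio(self, rng):
        ones = np.ones(100_000, dtype=np.int8)
        child = mendelian_cross(ones, ones, rng)
        props = np.bincount(child, minlength=3) / len(child)
        assert abs(props[0] - 0.25) < 0.01
        assert abs(props[1] - 0.50) < 0.01
        assert abs(props[2] - 0.25) < 0.01

    def test_marginal_expectation_mid_parent(self, rng):
        g1 = rng.integers(0, 3, 200).astype(np.int8)
        g2 = rng.integers(0, 3, 200).astype(np.int8)
        crosses = np.stack([mendelian_cross(g1, g2, rng) for _ in range(10_000)])
        expect = (g1 + g2) / 2.0
        se = np.sqrt(0.5 / 10_000)  # var(child dose) <= 0.5 per locus
        assert np.abs(crosses.mean(axis=0) - expect).max() < 5 * np.sqrt(0.5 / 10_000) + 0.02
        assert np.abs(crosses.mean(axis=0) - expect).mean() < 3 * se + 0.01

    def test_missing_parent_rejected(self, rng):
        from geoloci import MISSING

        g = np.array([0, MISSING], dtype=np.int8)
        with pytest.raises(InputError, match="impute"):
            mendelian_cross(g, g, rng)


class TestInterpolateCoordinates:
    def test_identical_parents_no_jitter(self, rng):
        c = np.array([-92.0, 36.0])
        np.testing.assert_array_equal(interpolate_coordinates(c, c, rng, 0.0), c)

    def test_equatorial_midpoint(self, rng):
        # force u = 0.5 by symmetry: average over many draws converges to midpoint
        c1, c2 = np.array([10.0, 0.0]), np.array([20.0, 0.0])
        pts = np.array([interpolate_coordinates(c1, c2, rng, 0.0) for _ in range(2000)])
        assert (pts[:, 1] == 0).all()  # stays on the equator
        assert abs(pts[:, 0].mean() - 15.0) < 0.1
        assert pts[:, 0].min() >= 12.5 - 1e-9 and pts[:, 0].max() <= 17.5 + 1e-9

    def test_distance_bound_to_parents(self, rng):
        c1, c2 = np.array([-92.0, 35.0]), np.array([-90.5, 36.5])
        sep = haversine_km(c1, c2)
        jit = 2.0
        for _ in range(1000):
            p = interpolate_coordinates(c1, c2, rng, jit)
            assert haversine_km(p, c1) <= sep + 3 * jit
            assert haversine_km(p, c2) <= sep + 3 * jit


def _toy_dataset(rng, sizes, centers):
    xy, labels = _clouds(rng, sizes, centers, spread=8.0)
    C = _coords(xy)
    n = len(xy)
    # clinal-ish doses so allele frequencies differ across clusters
    p = np.clip(0.2 + 0.3 * labels[:, None] + rng.normal(0, 0.05, (n, 300)), 0.05, 0.95)
    doses = rng.binomial(2, p).astype(np.int8)
    G = GenotypeMatrix(
        C.sample_ids, np.array([f"l{j}" for j in range(300)], dtype=object), doses
    )
    centroids = unproject_km(np.asarray(centers, float), np.array([-92.0, 36.0]))
    clus = SpatialClustering(labels, len(sizes), 0.8, centroids)
    return G, C, clus


class TestOversample:
    def test_balanced_clusters_no_synthetics(self, rng):
        G, C, clus = _toy_dataset(rng, (30, 30), [(0, 0), (300, 0)])
        aug = oversample(G, C, clus, rng=rng)
        assert aug.n_synthetic == 0

    def test_deficit_arithmetic(self, rng):
        G, C, clus = _toy_dataset(rng, (50, 10), [(0, 0), (300, 0)])
        aug = oversample(G, C, clus, rng=rng)
        assert aug.n_synthetic == 40
        assert (aug.labels[aug.is_synthetic] == 1).all()
        sizes = np.bincount(aug.labels)
        assert sizes[0] == sizes[1] == 50

    def test_real_rows_bit_identical(self, rng):
        G, C, clus = _toy_dataset(rng, (40, 15), [(0, 0), (300, 0)])
        aug = oversample(G, C, clus, rng=rng)
        n = G.n_samples
        assert np.array_equal(aug.doses[:n], G.doses)
        np.testing.assert_array_equal(aug.lonlat[:n], C.lonlat)
        assert not aug.is_synthetic[:n].any()

    def test_synthetic_allele_frequencies_match_cluster(self, rng):
        G, C, clus = _toy_dataset(rng, (100, 20), [(0, 0), (300, 0)])
        aug = oversample(G, C, clus, rng=rng)
        syn = aug.is_synthetic & (aug.labels == 1)
        real = ~aug.is_synthetic & (aug.labels == 1)
        f_syn = aug.doses[syn].mean(axis=0) / 2.0
        f_real = aug.doses[real].mean(axis=0) / 2.0
        assert np.abs(f_syn - f_real).mean() < 0.05

    def test_singleton_cluster_skipped(self, rng):
        G, C, clus = _toy_dataset(rng, (20, 1), [(0, 0), (300, 0)])
        aug = oversample(G, C, clus, rng=rng)
        assert aug.n_synthetic == 0

    def test_all_singletons_error(self, rng):
        G, C, clus = _toy_dataset(rng, (1, 1), [(0, 0), (300, 0)])
        with pytest.raises(AugmentationError):
            oversample(G, C, clus, rng=rng)

    def test_stratum_median_target_bounded_imbalance(self, rng):
        G, C, clus = _toy_dataset(
            rng, (60, 30, 25, 20, 10), [(0, 0), (250, 0), (0, 250), (250, 250), (120, 120)]
        )
        aug = oversample(G, C, clus, rng=rng, n_bins=3, target="stratum-median")
        sizes = np.bincount(aug.labels, minlength=5)
        # every cluster reaches at least its stratum's median size, so the
        # raw 6:1 imbalance strictly shrinks without forcing full balance
        before = np.bincount(clus.labels, minlength=5)
        assert (sizes >= before).all()
        assert sizes.max() / sizes.min() < before.max() / before.min()

    def test_parent_audit_recorded(self, rng):
        G, C, clus = _toy_dataset(rng, (30, 10), [(0, 0), (300, 0)])
        aug = oversample(G, C, clus, rng=rng)
        frame = aug.audit_frame()
        assert len(frame) == aug.n_synthetic
        assert set(frame["parent_1"]) <= set(G.sample_ids)


class TestStratifiedSplit:
    def test_proportional_allocation_two_clusters(self, rng):
        xy, labels = _clouds(rng, (40, 40), [(0, 0), (300, 0)])
        C = _coords(xy)
        clus = SpatialClustering(labels, 2, 0.9, np.zeros((2, 2)))
        split = stratified_split(C, clus, (0.75, 0.125, 0.125), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (60, 10, 10)
        for c in (0, 1):
            assert split.allocation[c] == (30, 5, 5)

    def test_disjoint_and_complete(self, ibd_features):
        _, C = ibd_features
        clus = cluster_coordinates(C, seed=1)
        split = stratified_split(C, clus, seed=1)
        all_idx = np.concatenate([split.train, split.validation, split.test])
        assert len(set(all_idx)) == len(C)

    def test_every_cluster_reaches_training(self, rng):
        xy, labels = _clouds(rng, (50, 3), [(0, 0), (300, 0)])
        C = _coords(xy)
        clus = SpatialClustering(labels, 2, 0.9, np.zeros((2, 2)))
        split = stratified_split(C, clus, seed=0)
        assert split.allocation[1][0] >= 1

    def test_seed_deterministic_and_row_order_invariant(self, rng):
        xy, labels = _clouds(rng, (30, 20), [(0, 0), (300, 0)])
        C = _coords(xy)
        clus = SpatialClustering(labels, 2, 0.9, np.zeros((2, 2)))
        s1 = stratified_split(C, clus, seed=5)
        s2 = stratified_split(C, clus, seed=5)
        np.testing.assert_array_equal(s1.train, s2.train)
        # permute rows: the chosen ID sets must be unchanged
        perm = np.random.default_rng(9).permutation(len(C))
        Cp = C.subset(perm)
        clusp = SpatialClustering(labels[perm], 2, 0.9, np.zeros((2, 2)))
        s3 = stratified_split(Cp, clusp, seed=5)
        ids = lambda c, idx: sorted(c.sample_ids[idx].tolist())
        assert ids(C, s1.train) == ids(Cp, s3.train)
        assert ids(C, s1.test) == ids(Cp, s3.test)

    def test_invalid_fractions(self, ibd_features):
        _, C = ibd_features
        clus = cluster_coordinates(C, seed=1)
        with pytest.raises(ConfigError):
            stratified_split(C, clus, (0.5, 0.2, 0.2))
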