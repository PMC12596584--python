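"""Spatial balancing: clustering, Mendelian oversampling, stratified splits.

Three related pieces:

* silhouette-selected k-means on projected coordinates to delimit
  spatial clusters;
* SMOTE-style synthetic oversampling that fills each cluster's deficit
  with Mendelian crosses of geographically proximate within-cluster
  parents, placed on the great-circle segment between them;
* a density-stratified train/validation/test split that represents
  every cluster proportionally instead of letting dense regions
  dominate the evaluation partitions.

Synthetic rows are tagged and enter training only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, CoordinateSet, GenotypeMatrix
from .errors import AugmentationError, ConfigError, DegenerateGeometryError, InputError
from .geometry import (
    pairwise_haversine_km,
    project_km,
    slerp_lonlat,
    unproject_km,
)

logger = logging.getLogger(__name__)


@dataclass
class SpatialClustering:
    """k-means cluster assignment with its silhouette-selected k."""

    labels: np.ndarray
    k: int
    mean_silhouette: float
    centroids: np.ndarray  # k × 2 lon/lat

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class AugmentedDataset:
    """Real rows plus Mendelian synthetic rows, with provenance."""

    sample_ids: np.ndarray
    doses: np.ndarray
    lonlat: np.ndarray
    labels: np.ndarray  # cluster per row
    is_synthetic: np.ndarray  # bool per row
    parents: np.ndarray  # object array of (id1, id2) or None

    @property
    def n_synthetic(self) -> int:
        return int(self.is_synthetic.sum())

    def audit_frame(self):
        import pandas as pd

        syn = self.is_synthetic
        return pd.DataFrame(
            {
                "synthetic_id": self.sample_ids[syn],
                "parent_1": [p[0] for p in self.parents[syn]],
                "parent_2": [p[1] for p in self.parents[syn]],
                "cluster": self.labels[syn],
                "lon": self.lonlat[syn, 0],
                "lat": self.lonlat[syn, 1],
            }
        )


@dataclass
class SplitIndices:
    """Disjoint train/validation/test (and unknown) index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    predict: np.ndarray
    allocation: dict  # cluster -> (n_train, n_val, n_test)


def cluster_coordinates(
    C: CoordinateSet,
    k_range: tuple[int, int] = (2, 10),
    seed: int | None = 0,
    n_restarts: int = 10,
) -> SpatialClustering:
    """k-means over projected km coordinates; k chosen by mean silhouette.

    Every k in ``k_range`` is fit with ``n_restarts`` seeded restarts;
    the k maximizing mean silhouette width wins, ties going to the
    smaller k.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n = len(C)
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max):
        raise ConfigError(f"invalid k_range {k_range}")
    k_max = min(k_max, n - 1)
    if n < k_min + 1:
        raise ConfigError(f"need at least {k_min + 1} samples to cluster")
    xy, origin = project_km(C.lonlat)
    if np.allclose(xy, xy[0], atol=1e-9):
        raise DegenerateGeometryError("all coordinates identical; cannot cluster")

    best = None
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(xy)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(xy, labels))
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, labels, km.cluster_centers_)
    if best is None:
        raise DegenerateGeometryError("clustering failed for every k in range")
    sil, k, labels, centers_xy = best
    centroids = unproject_km(centers_xy, origin)
    logger.info("cluster_coordinates: k=%d, mean silhouette %.3f", k, sil)
    return SpatialClustering(labels, k, sil, centroids)


def mendelian_cross(
    g1: np.ndarray, g2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Cross two dose vectors: each parent transmits one allele per locus.

    A parent with dose g transmits the alternate allele with probability
    g/2; the child dose is the sum of the two transmitted alleles, so
    E[child] = (g1 + g2)/2 per locus.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise InputError("parent dose vectors differ in length")
    if np.any(g1 == MISSING) or np.any(g2 == MISSING):
        raise InputError("parents contain missing doses; impute before crossing")
    a1 = rng.random(g1.shape) < (g1 / 2.0)
    a2 = rng.random(g2.shape) < (g2 / 2.0)
    return (a1.astype(np.int8) + a2.astype(np.int8))


def interpolate_coordinates(
    c1: np.ndarray,
    c2: np.ndarray,
    rng: np.random.Generator,
    jitter_km: float = 1.0,
) -> np.ndarray:
    """Place a synthetic sample between two parents.

    The point sits at fraction u ~ Uniform(0.25, 0.75) along the
    great-circle segment (bounded away from the endpoints so synthetic
    samples never duplicate a real one), plus isotropic Gaussian jitter
    with scale ``jitter_km``.
    """
    u = rng.uniform(0.25, 0.75)
    p = slerp_lonlat(np.asarray(c1, float), np.asarray(c2, float), u)
    if jitter_km > 0:
        dx, dy = rng.normal(0.0, jitter_km, size=2)
        p = unproject_km(np.array([[dx, dy]]), p)[0]
    return p


def oversample(
    G: GenotypeMatrix,
    C: CoordinateSet,
    clustering: SpatialClustering,
    max_neighbors: int = 20,
    n_bins: int = 6,
    rng: np.random.Generator | None = None,
    target: str = "global-max",
    jitter_km: float = 1.0,
) -> AugmentedDataset:
    """Fill spatial-cluster deficits with Mendelian synthetic samples.

    Each cluster's deficit is the gap to the balancing target: the
    largest cluster's size (``global-max``, the default) or the median
    size of the cluster's density stratum (``stratum-median``, using
    ``n_bins`` equal-frequency bins of cluster density). Deficits are
    filled by drawing a seed sample uniformly from the cluster, a
    partner uniformly from its min(max_neighbors, cluster_size − 1)
    geographically nearest within-cluster neighbors, and emitting a
    Mendelian-cross genotype at an interpolated location. Size-1
    clusters are skipped with a warning (no self-crossing).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if max_neighbors < 1:
        raise ConfigError("max_neighbors must be >= 1")
    if G.missing_mask.any():
        raise InputError("impute missing doses before oversampling")
    labels = clustering.labels
    if len(labels) != G.n_samples:
        raise InputError("clustering does not cover all samples")

    sizes = np.bincount(labels, minlength=clustering.k)
    if np.all(sizes[sizes > 0] == 1):
        raise AugmentationError("all clusters are singletons; cannot oversample")

    # Density strata: equal-frequency bins of cluster density (size per
    # unit of cluster spatial spread is unnecessary here — the balancing
    # semantics only need a ranking of cluster sizes).
    occupied = np.flatnonzero(sizes > 0)
    if target == "global-max":
        targets = {c: int(sizes.max()) for c in occupied}
    elif target == "stratum-median":
        order = np.argsort(sizes[occupied], kind="stable")
        strata = np.array_split(occupied[order], min(n_bins, len(occupied)))
        targets = {}
        for stratum in strata:
            med = int(np.median(sizes[stratum]))
            for c in stratum:
                targets[c] = max(med, int(sizes[c]))
    else:
        raise ConfigError(f"unknown balancing target {target!r}")

    geo = pairwise_haversine_km(C.lonlat)
    syn_doses, syn_lonlat, syn_labels, syn_parents, syn_ids = [], [], [], [], []
    counter = 0
    for c in occupied:
        deficit = targets[c] - int(sizes[c])
        if deficit <= 0:
            continue
        members = np.flatnonzero(labels == c)
        if len(members) == 1:
            logger.warning("oversample: cluster %d has a single member; skipped", c)
            continue
        sub_geo = geo[np.ix_(members, members)]
        k_nbr = min(max_neighbors, len(members) - 1)
        for _ in range(deficit):
            si = rng.integers(len(members))
            order = np.argsort(np.where(np.arange(len(members)) == si, np.inf, sub_geo[si]),
                               kind="stable")
            pi = order[rng.integers(k_nbr)]
            i, j = members[si], members[pi]
            child = mendelian_cross(G.doses[i], G.doses[j], rng)
            loc = interpolate_coordinates(C.lonlat[i], C.lonlat[j], rng, jitter_km)
            syn_doses.append(child)
            syn_lonlat.append(loc)
            syn_labels.append(c)
            syn_parents.append((G.sample_ids[i], G.sample_ids[j]))
            syn_ids.append(f"syn_{counter:05d}")
            counter += 1

    n_real = G.n_samples
    if syn_doses:
        doses = np.vstack([G.doses, np.array(syn_doses, dtype=np.int8)])
        lonlat = np.vstack([C.lonlat, np.array(syn_lonlat)])
        all_labels = np.concatenate([labels, np.array(syn_labels)])
        ids = np.concatenate([G.sample_ids, np.array(syn_ids, dtype=object)])
    else:
        doses, lonlat, all_labels, ids = G.doses.copy(), C.lonlat.copy(), labels.copy(), G.sample_ids.copy()
    parents = np.empty(len(ids), dtype=object)
    parents[n_real:] = syn_parents
    is_syn = np.zeros(len(ids), dtype=bool)
    is_syn[n_real:] = True
    logger.info("oversample: emitted %d synthetic samples", counter)
    return AugmentedDataset(ids, doses, lonlat, all_labels, is_syn, parents)


def stratified_split(
    C: CoordinateSet,
    clustering: SpatialClustering,
    fractions: tuple[float, float, float] = (0.75, 0.125, 0.125),
    seed: int | None = 0,
) -> SplitIndices:
    """Per-cluster proportional train/val/test allocation.

    Within each cluster, counts follow largest-remainder rounding of
    cluster_size × fraction (remainder ties go train > val > test), and
    members are assigned after a seeded shuffle of the cluster's
    ID-sorted sample list — so the split depends only on the ID set, the
    clustering, and the seed, never on input row order.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must be positive and sum to 1, got {fractions}")
    labels = clustering.labels
    if len(labels) != len(C):
        raise InputError("clustering does not cover all samples")

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    allocation: dict[int, tuple[int, int, int]] = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        # Order by sample ID so the allocation is row-order invariant.
        members = members[np.argsort(C.sample_ids[members].astype(str), kind="stable")]
        n_c = len(members)
        quota = np.array([n_c * f for f in fractions])
        counts = np.floor(quota).astype(int)
        rem = quota - counts
        for _ in range(n_c - counts.sum()):
            j = int(np.argmax(rem))
            counts[j] += 1
            rem[j] = -1.0
        if n_c >= 3 and counts[0] == 0:  # every non-trivial cluster reaches training
            j = int(np.argmax(counts[1:])) + 1
            counts[j] -= 1
            counts[0] += 1
        perm = rng.permutation(n_c)
        shuffled = members[perm]
        train.extend(shuffled[: counts[0]])
        val.extend(shuffled[counts[0] : counts[0] + counts[1]])
        test.extend(shuffled[counts[0] + counts[1] :])
        allocation[int(c)] = tuple(int(x) for x in counts)

    return SplitIndices(
        np.array(sorted(train), dtype=int),
        np.array(sorted(val), dtype=int),
        np.array(sorted(test), dtype=int),
        np.array([], dtype=int),
        allocation,
    )
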