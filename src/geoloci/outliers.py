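"""Geo-genetic outlier detection against isolation-by-distance.

Under isolation by distance (IBD), a sample's genetic neighbors are its
geographic neighbors. Translocated individuals break that expectation:
their genotype points to one place, their collection record to another.
This module adapts the reciprocal KNN cross-prediction idea of the
GGOutlieR approach: predict each sample's location from its K
genetically nearest neighbors (and, reciprocally, its genetic position
from its K geographically nearest neighbors), fit a gamma null to the
resulting error distributions, and flag samples with small upper-tail
p-values in either direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .datatypes import CoordinateSet, FeatureMatrix, GenotypeMatrix
from .errors import (
    ConfigError,
    DegenerateDistributionError,
    GeolociError,
    TooFewSamplesError,
)
from .geometry import haversine_km, pairwise_haversine_km, project_km, unproject_km

logger = logging.getLogger(__name__)

#: Principal components retained for the genetic neighbor space.
DEFAULT_N_PCS = 10


@dataclass
class OutlierReport:
    """Per-sample cross-prediction errors, gamma p-values, and flags."""

    sample_ids: np.ndarray
    geo_error: np.ndarray  # km, location predicted from genetic neighbors
    gen_error: np.ndarray  # PC-space distance, predicted from geographic neighbors
    p_geo: np.ndarray
    p_gen: np.ndarray
    flagged: np.ndarray  # bool
    reason: np.ndarray  # "", "geo", "gen", "both"
    alpha: float

    @property
    def flagged_ids(self) -> np.ndarray:
        return self.sample_ids[self.flagged]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "geo_error_km": self.geo_error,
                "gen_error": self.gen_error,
                "p_geo": self.p_geo,
                "p_gen": self.p_gen,
                "flagged": self.flagged,
                "reason": self.reason,
            }
        )


def genetic_pcs(F: FeatureMatrix, n_pcs: int = DEFAULT_N_PCS) -> np.ndarray:
    """Top principal components of the column-standardized feature matrix."""
    X = F.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_pcs = min(n_pcs, min(Z.shape) - 1) or 1
    from sklearn.decomposition import PCA

    return PCA(n_components=n_pcs, svd_solver="full").fit_transform(Z)


def _knn_weighted_prediction(
    dist: np.ndarray, targets: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance-weighted mean of each row's K nearest targets (self excluded).

    Ties in distance resolve by sample order (stable argsort). A zero
    distance gets the full weight of its tied group. Also returns each
    sample's neighborhood dispersion — the weighted RMS spread of the
    neighbor targets about the prediction — used to put cross-
    prediction errors from dense and sparse neighborhoods on a common
    scale before null fitting.
    """
    n = dist.shape[0]
    pred = np.empty((n, targets.shape[1]))
    spread = np.empty(n)
    for i in range(n):
        d = dist[i].copy()
        d[i] = np.inf
        nbr = np.argsort(d, kind="stable")[:K]
        dn = d[nbr]
        if np.any(dn == 0):
            w = (dn == 0).astype(float)
        else:
            w = 1.0 / dn
        w /= w.sum()
        pred[i] = w @ targets[nbr]
        spread[i] = np.sqrt(float((w * ((targets[nbr] - pred[i]) ** 2).sum(axis=1)).sum()))
    return pred, spread


def _cross_errors_with_scale(
    F: FeatureMatrix,
    C: CoordinateSet,
    K: int,
    mode: str,
    n_pcs: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(C)
    if not (1 <= K <= n - 1):
        raise ConfigError(f"K={K} out of range [1, {n - 1}]")
    pcs = genetic_pcs(F, n_pcs)

    if mode == "geo_from_gen":
        gd = np.sqrt(((pcs[:, None, :] - pcs[None, :, :]) ** 2).sum(axis=-1))
        xy, origin = project_km(C.lonlat)
        pred_xy, spread = _knn_weighted_prediction(gd, xy, K)
        pred = unproject_km(pred_xy, origin)
        err = np.asarray(
            haversine_km(pred[:, 0], pred[:, 1], C.lon, C.lat), dtype=float
        )
        return err, spread
    if mode == "gen_from_geo":
        geo = pairwise_haversine_km(C.lonlat)
        pred_pcs, spread = _knn_weighted_prediction(geo, pcs, K)
        err = np.sqrt(((pred_pcs - pcs) ** 2).sum(axis=1))
        return err, spread
    raise ConfigError(f"unknown mode {mode!r}")


def knn_cross_errors(
    F: FeatureMatrix,
    C: CoordinateSet,
    K: int = 20,
    mode: str = "geo_from_gen",
    n_pcs: int = DEFAULT_N_PCS,
) -> np.ndarray:
    """Reciprocal KNN cross-prediction error for each sample.

    ``geo_from_gen``: predict each sample's location as the inverse-
    distance-weighted mean of its K genetically nearest neighbors'
    coordinates (projected km, self excluded); error is the Haversine
    distance to the recorded location in km.

    ``gen_from_geo``: predict the sample's top-PC genetic vector from
    its K geographically nearest neighbors; error is Euclidean distance
    in PC space.
    """
    err, _ = _cross_errors_with_scale(F, C, K, mode, n_pcs)
    return err


def fit_gamma_null(errors: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) for an error null distribution.

    Zeros are replaced by half the smallest positive value so the
    density is defined; requires >= 30 values and a non-degenerate
    spread.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 30:
        raise GeolociError(f"gamma null needs >= 30 errors, got {e.size}")
    if np.any(e < 0) or not np.isfinite(e).all():
        raise GeolociError("errors must be finite and non-negative")
    pos = e[e > 0]
    if pos.size == 0 or np.ptp(e) < 1e-12 * max(1.0, e.max()):
        raise DegenerateDistributionError("error distribution is constant")
    e = np.where(e > 0, e, pos.min() / 2.0)
    shape, _, scale = gamma_dist.fit(e, floc=0)
    return float(shape), float(scale)


def _gamma_pvalues(errors: np.ndarray, null_mask: np.ndarray) -> np.ndarray:
    shape, scale = fit_gamma_null(errors[null_mask])
    return gamma_dist.sf(errors, shape, scale=scale)


def flag_outliers(
    F: FeatureMatrix,
    C: CoordinateSet,
    K: int = 20,
    alpha: float = 0.05,
    iterate: bool = False,
    n_pcs: int = DEFAULT_N_PCS,
) -> OutlierReport:
    """Build the full outlier report: errors, gamma p-values, flags.

    A sample is flagged when its upper-tail gamma p-value in either the
    geographic or the genetic direction falls below ``alpha``. The null
    is fit on squared cross-prediction errors normalized by each
    sample's neighborhood dispersion: a squared isotropic prediction
    error is gamma-distributed, and the normalization removes the
    dense-versus-sparse neighborhood scale gradient that would
    otherwise thicken the tail. With ``iterate`` (off by default: the
    regularized statistic already unmasks heavy outliers, and any refit
    slightly inflates the null false-positive rate) the nulls are refit
    once excluding decisively flagged samples and p-values recomputed.
    """
    if not (0 <= alpha < 1):
        raise ConfigError("alpha must be in [0, 1)")
    K = min(K, len(C) - 1)
    geo_err, geo_scale = _cross_errors_with_scale(F, C, K, "geo_from_gen", n_pcs)
    gen_err, gen_scale = _cross_errors_with_scale(F, C, K, "gen_from_geo", n_pcs)
    # Regularize the per-sample scale with the cohort median so a sample
    # whose neighbors happen to coincide (spread → 0) cannot blow up its
    # own statistic.
    geo_stat = geo_err**2 / (geo_scale**2 + np.median(geo_scale) ** 2)
    gen_stat = gen_err**2 / (gen_scale**2 + np.median(gen_scale) ** 2)

    keep = np.ones(len(C), dtype=bool)
    p_geo = _gamma_pvalues(geo_stat, keep)
    p_gen = _gamma_pvalues(gen_stat, keep)
    if alpha == 0:
        flagged = np.zeros(len(C), dtype=bool)
    else:
        flagged = (p_geo < alpha) | (p_gen < alpha)
        # Refit excluding only decisive first-pass outliers, at a Bonferroni-
        # style threshold alpha/(10n) per tail: a planted translocation sits
        # many null SDs out and masks itself by inflating the fitted scale,
        # while on outlier-free data the smallest p-value is around 1/n, so
        # the refit leaves the null untouched and the false-positive rate
        # uninflated.
        decisive_p = alpha / (100.0 * len(C))
        decisive = (p_geo < decisive_p) | (p_gen < decisive_p)
        if iterate and decisive.any() and (~decisive).sum() >= 30:
            keep = ~decisive
            p_geo = _gamma_pvalues(geo_stat, keep)
            p_gen = _gamma_pvalues(gen_stat, keep)
            flagged = (p_geo < alpha) | (p_gen < alpha)

    reason = np.array(
        [
            ("both" if (pg < alpha and pn < alpha) else "geo" if pg < alpha else "gen")
            if fl
            else ""
            for pg, pn, fl in zip(p_geo, p_gen, flagged)
        ],
        dtype=object,
    )
    if flagged.any():
        logger.info("flag_outliers: flagged %d of %d samples (alpha=%g)",
                    int(flagged.sum()), len(C), alpha)
    return OutlierReport(
        C.sample_ids, geo_err, gen_err, p_geo, p_gen, flagged, reason, alpha
    )


def prune_training(
    G: GenotypeMatrix,
    C: CoordinateSet,
    report: OutlierReport,
    min_remaining: int = 20,
) -> tuple[GenotypeMatrix, CoordinateSet]:
    """Remove flagged samples from the training data (never the unknowns).

    Raises when fewer than ``min_remaining`` samples would remain.
    """
    flagged = set(report.flagged_ids.tolist())
    if not flagged:
        return G, C
    missing = set(G.sample_ids.tolist()) - set(report.sample_ids.tolist())
    if missing:
        raise GeolociError(f"outlier report does not cover samples: {sorted(missing)[:5]}")
    keep = np.array([s not in flagged for s in G.sample_ids])
    if keep.sum() < min_remaining:
        raise TooFewSamplesError(
            f"pruning would leave {int(keep.sum())} < {min_remaining} training samples"
        )
    removed = G.sample_ids[~keep]
    logger.info("prune_training: removed %d flagged samples: %s",
                len(removed), ", ".join(map(str, removed[:10])))
    idx = keep.nonzero()[0]
    c_pos = {s: i for i, s in enumerate(C.sample_ids)}
    c_idx = np.array([c_pos[s] for s in G.sample_ids[idx]])
    return G.subset_samples(idx), C.subset(c_idx)
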