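"""Inverse sampling-density sample weights.

Spatial sampling effort in landscape genetics is rarely uniform: dense
hotspots (road access, management zones) dominate least-squares fits.
This module estimates per-sample sampling density in samples/km² with a
Gaussian kernel density estimate on locally projected coordinates and
derives loss weights proportional to 1/density, optionally quantile-
clipped and mean-normalized to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .datatypes import CoordinateSet
from .errors import DegenerateGeometryError, GeolociError
from .geometry import project_km

logger = logging.getLogger(__name__)


@dataclass
class SampleWeights:
    """Per-sample inverse-density weights with their source densities."""

    sample_ids: np.ndarray
    weight: np.ndarray  # strictly positive; mean 1 when normalized
    density: np.ndarray  # samples per km²
    normalized: bool

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.weight <= 0) or not np.isfinite(self.weight).all():
            raise GeolociError("weights must be strictly positive and finite")
        if self.normalized and abs(self.weight.mean() - 1.0) > 1e-9:
            raise GeolociError("normalized weights must have mean 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample_id": self.sample_ids, "density": self.density, "weight": self.weight}
        )


def estimate_density(
    C: CoordinateSet, bandwidth: str | float = "scott"
) -> np.ndarray:
    """Gaussian-KDE sampling density (samples/km²) at each sample location.

    ``bandwidth`` is "scott", "silverman", or a fixed isotropic bandwidth
    in km. The KDE is evaluated on an equirectangular projection about
    the data centroid; the pdf (which integrates to 1 over km²) is
    multiplied by n to give samples/km².
    """
    n = len(C)
    if n < 2:
        raise DegenerateGeometryError("density estimation needs >= 2 samples")
    xy, _ = project_km(C.lonlat)
    if np.allclose(xy, xy[0], atol=1e-9):
        raise DegenerateGeometryError("all coordinates identical; no density gradient")

    if isinstance(bandwidth, str):
        if bandwidth not in ("scott", "silverman"):
            raise GeolociError(f"unknown bandwidth rule {bandwidth!r}")
        try:
            kde = gaussian_kde(xy.T, bw_method=bandwidth)
            pdf = kde(xy.T)
        except np.linalg.LinAlgError:
            # Collinear points: singular covariance; fall back to an
            # isotropic kernel with Scott's per-dimension factor.
            h = float(np.std(xy, axis=0).max()) * n ** (-1.0 / 6.0)
            pdf = _isotropic_kde(xy, max(h, 1e-6))
    else:
        h = float(bandwidth)
        if h <= 0:
            raise GeolociError("fixed bandwidth must be positive km")
        pdf = _isotropic_kde(xy, h)

    density = n * pdf
    density = np.maximum(density, np.finfo(float).tiny)
    return density


def _isotropic_kde(xy: np.ndarray, h_km: float) -> np.ndarray:
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
    k = np.exp(-d2 / (2.0 * h_km**2)) / (2.0 * np.pi * h_km**2)
    return k.mean(axis=1)


def inverse_density_weights(
    C: CoordinateSet,
    density: np.ndarray,
    normalize: bool = True,
    clip_quantiles: tuple[float, float] | None = (0.01, 0.99),
) -> SampleWeights:
    """Weights ∝ 1/density, optionally quantile-clipped then mean-normalized.

    Clipping (default 1st/99th percentile of the raw inverse densities)
    stops single isolated samples from dominating a weighted loss; it is
    logged whenever it changes any weight.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density <= 0) or not np.isfinite(density).all():
        raise GeolociError("densities must be positive and finite")
    w = 1.0 / density
    if clip_quantiles is not None:
        lo, hi = np.quantile(w, clip_quantiles)
        clipped = int(((w < lo) | (w > hi)).sum())
        if clipped:
            logger.info("inverse_density_weights: clipped %d weights to quantiles %s",
                        clipped, clip_quantiles)
        w = np.clip(w, lo, hi)
    if normalize:
        w = w / w.mean()
    return SampleWeights(C.sample_ids, w, density, normalized=normalize)
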