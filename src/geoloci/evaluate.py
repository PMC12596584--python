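"""Haversine accuracy metrics, error surfaces, and report rendering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CoordinateSet
from .errors import DegenerateGeometryError, InputError
from .geometry import EARTH_RADIUS_KM, haversine_km as _haversine_lonlat, project_km

logger = logging.getLogger(__name__)


def haversine_km(p1, p2) -> float | np.ndarray:
    """Great-circle distance in km between (lon, lat) points in degrees.

    d = 2R·asin(√(sin²(Δφ/2) + cos φ₁·cos φ₂·sin²(Δλ/2))), R = 6371.0 km.
    Accepts single points or broadcastable arrays of shape (..., 2).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return _haversine_lonlat(p1[..., 0], p1[..., 1], p2[..., 0], p2[..., 1])


@dataclass
class EvaluationSummary:
    """Per-sample Haversine errors with aggregate statistics."""

    sample_ids: np.ndarray
    errors_km: np.ndarray
    mean_km: float
    sd_km: float
    median_km: float
    iqr_km: float
    per_cluster: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "error_km": self.errors_km})

    def __str__(self) -> str:  # the field's reporting style: "mean ± SD km"
        return (
            f"mean {self.mean_km:.2f} ± {self.sd_km:.2f} km, "
            f"median {self.median_km:.2f} km (IQR {self.iqr_km:.2f})"
        )


def summarize_errors(
    predictions: CoordinateSet,
    truths: CoordinateSet,
    cluster_labels: np.ndarray | None = None,
) -> EvaluationSummary:
    """Per-sample Haversine error plus mean ± SD (n−1), median, and IQR."""
    if len(predictions) != len(truths) or not np.array_equal(
        predictions.sample_ids, truths.sample_ids
    ):
        raise InputError("predictions and truths are not paired by sample ID")
    err = np.asarray(
        _haversine_lonlat(predictions.lon, predictions.lat, truths.lon, truths.lat),
        dtype=float,
    )
    q1, q3 = np.percentile(err, [25, 75])
    per_cluster = None
    if cluster_labels is not None:
        per_cluster = (
            pd.DataFrame({"cluster": cluster_labels, "error_km": err})
            .groupby("cluster")["error_km"]
            .agg(["mean", "std", "median", "count"])
            .reset_index()
        )
    sd = float(np.std(err, ddof=1)) if len(err) > 1 else 0.0
    return EvaluationSummary(
        predictions.sample_ids,
        err,
        float(err.mean()),
        sd,
        float(np.median(err)),
        float(q3 - q1),
        per_cluster,
    )


def error_surface(
    locations: CoordinateSet,
    errors_km: np.ndarray,
    grid_size: int = 50,
    power: float = 2.0,
    n_neighbors: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-distance-weighted mean-error field on a regular lon/lat grid.

    Returns (grid_lon, grid_lat, field) with NaN outside the convex hull
    of the sample locations. IDW is exact at grid nodes coincident with
    a sample.
    """
    errors_km = np.asarray(errors_km, dtype=float)
    pts = locations.lonlat
    if len(np.unique(pts, axis=0)) < 3:
        raise DegenerateGeometryError("error surface needs >= 3 distinct locations")
    lon_g = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size)
    lat_g = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size)
    xy, origin = project_km(pts)

    from scipy.spatial import Delaunay, cKDTree

    try:
        hull = Delaunay(pts)
    except Exception as exc:
        raise DegenerateGeometryError(f"degenerate geometry for hull: {exc}") from exc
    tree = cKDTree(xy)
    k = min(n_neighbors, len(pts))

    gl, gt = np.meshgrid(lon_g, lat_g)
    nodes = np.column_stack([gl.ravel(), gt.ravel()])
    inside = hull.find_simplex(nodes) >= 0
    node_xy, _ = project_km(nodes, origin)
    dist, idx = tree.query(node_xy, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    field = np.full(len(nodes), np.nan)
    exact = dist[:, 0] < 1e-9
    field[exact & inside] = errors_km[idx[exact & inside, 0]]
    rest = inside & ~exact
    w = 1.0 / dist[rest] ** power
    field[rest] = (w * errors_km[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return lon_g, lat_g, field.reshape(grid_size, grid_size)


def render_reports(
    out_dir: str | Path,
    summary: EvaluationSummary | None = None,
    history: pd.DataFrame | None = None,
    prediction_clouds: dict | None = None,
    truths: CoordinateSet | None = None,
    surface: tuple | None = None,
) -> list[str]:
    """Write the diagnostic figure/table manifest; returns written file names.

    Emits whatever inputs are present: per-sample error CSV + box plot,
    loss curves, bootstrap prediction maps with centroid/truth markers,
    and the IDW error-surface map. Deterministic for fixed inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if summary is not None:
        summary.to_frame().to_csv(out / "per_sample_errors.csv", index=False)
        written.append("per_sample_errors.csv")
        stats = pd.DataFrame(
            [
                {
                    "mean_km": summary.mean_km,
                    "sd_km": summary.sd_km,
                    "median_km": summary.median_km,
                    "iqr_km": summary.iqr_km,
                    "n": len(summary.errors_km),
                }
            ]
        )
        stats.to_csv(out / "error_summary.csv", index=False)
        written.append("error_summary.csv")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot(summary.errors_km)
        ax.set_ylabel("Haversine error (km)")
        fig.savefig(out / "error_boxplot.png", dpi=120)
        plt.close(fig)
        written.append("error_boxplot.png")
        if summary.per_cluster is not None:
            summary.per_cluster.to_csv(out / "per_cluster_errors.csv", index=False)
            written.append("per_cluster_errors.csv")

    if history is not None:
        history.to_csv(out / "training_history.csv", index=False)
        written.append("training_history.csv")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(history["epoch"], history["train_loss"], label="train")
        ax.plot(history["epoch"], history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        fig.savefig(out / "loss_curves.png", dpi=120)
        plt.close(fig)
        written.append("loss_curves.png")

    if prediction_clouds:
        rows = []
        for sid, cloud in prediction_clouds.items():
            for b, (lo, la) in enumerate(cloud):
                rows.append({"sample_id": sid, "replicate": b, "lon": lo, "lat": la})
        pd.DataFrame(rows).to_csv(out / "bootstrap_predictions.csv", index=False)
        written.append("bootstrap_predictions.csv")
        fig, ax = plt.subplots(figsize=(5, 5))
        truth_pos = (
            {s: i for i, s in enumerate(truths.sample_ids)} if truths is not None else {}
        )
        for sid, cloud in prediction_clouds.items():
            cloud = np.asarray(cloud)
            ax.scatter(cloud[:, 0], cloud[:, 1], s=4, alpha=0.3)
            cen = cloud.mean(axis=0)
            ax.scatter(*cen, marker="x", color="black", s=40)
            if sid in truth_pos:
                i = truth_pos[sid]
                ax.scatter(truths.lon[i], truths.lat[i], marker="^", color="red", s=40)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        fig.savefig(out / "bootstrap_map.png", dpi=120)
        plt.close(fig)
        written.append("bootstrap_map.png")

    if surface is not None:
        lon_g, lat_g, field = surface
        fig, ax = plt.subplots(figsize=(5, 4))
        pm = ax.pcolormesh(lon_g, lat_g, field, shading="auto")
        fig.colorbar(pm, ax=ax, label="mean error (km)")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        fig.savefig(out / "error_surface.png", dpi=120)
        plt.close(fig)
        written.append("error_surface.png")

    (out / "manifest.txt").write_text("\n".join(written) + "\n")
    logger.info("render_reports: wrote %d files to %s", len(written), out)
    return written
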