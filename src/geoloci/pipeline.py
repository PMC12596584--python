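"""End-to-end workflow orchestration and model persistence.

Stage order: load/filter/impute → align and hold out unknowns →
stratified split → (optional) outlier pruning of the training partition
→ (optional) inverse-density weights → (optional) Mendelian
oversampling of training only → (optional) hyperparameter search →
training → bootstrap prediction → evaluation and reports. Every
optional stage's on/off state is logged; a single seed fixes every
source of randomness, so identical configs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .augment import cluster_coordinates, oversample as _oversample, stratified_split
from .config import RunConfig
from .datatypes import CoordinateSet, FeatureMatrix, GenotypeMatrix
from .errors import CheckpointError, GeolociError
from .evaluate import render_reports, summarize_errors
from .geometry import haversine_km
from .nn import GeoMLP, ModelSpec, TrainConfig, TrainedGeoModel, predict, resolve_width, train
from .outliers import flag_outliers, prune_training
from .tuning import SearchSpace, bootstrap_predict, search_hyperparameters
from .weights import estimate_density, inverse_density_weights

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GeolociError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns a result dict with paths and metrics."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "effective_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)

    # -- load and preprocess
    G = gio.read_vcf(config.vcf)
    C_all = gio.read_coordinates(config.coordinates, config.lat_lon_order)
    G = gio.filter_minor_allele_count(G, config.mac_min)
    G = gio.impute_missing(G, config.impute_strategy, seed=config.seed)
    G_known_full, C, unknown_ids = gio.align_samples(G, C_all)

    F_all = gio.doses_to_features(G)
    if config.embedding != "none":
        F_all = gio.embed_genotypes(
            F_all, config.embedding, config.n_components, seed=config.seed
        )
    pos = {s: i for i, s in enumerate(F_all.sample_ids)}
    known_idx = np.array([pos[s] for s in G_known_full.sample_ids])
    unk_idx = np.array([pos[s] for s in unknown_ids], dtype=int)
    F_known = F_all.subset(known_idx)
    F_unknown = F_all.subset(unk_idx) if len(unk_idx) else None
    G_known = G_known_full

    # -- split
    clustering = cluster_coordinates(C, config.k_range, seed=config.seed)
    split = stratified_split(C, clustering, config.split_fractions, seed=config.seed)
    logger.info("split: train %d / val %d / test %d / unknown %d",
                len(split.train), len(split.validation), len(split.test), len(unknown_ids))

    tr, va, te = split.train, split.validation, split.test
    F_tr, C_tr = F_known.subset(tr), C.subset(tr)
    G_tr = G_known.subset_samples(tr)
    labels_tr = clustering.labels[tr]

    # -- optional outlier pruning (training partition only)
    outlier_report = None
    logger.info("outlier_detection: %s", "on" if config.outlier_detection else "off")
    if config.outlier_detection:
        outlier_report = flag_outliers(
            F_tr, C_tr, K=config.max_neighbors, alpha=config.outlier_alpha
        )
        outlier_report.to_frame().to_csv(out / "outlier_report.csv", index=False)
        keep = ~outlier_report.flagged
        G_tr, C_tr = prune_training(G_tr, C_tr, outlier_report)
        F_tr = F_tr.subset(np.flatnonzero(keep))
        labels_tr = labels_tr[keep]

    # -- optional oversampling (training only)
    logger.info("oversample: %s", "on" if config.oversample else "off")
    if config.oversample:
        from .augment import SpatialClustering

        sub_cluster = SpatialClustering(
            labels_tr, clustering.k, clustering.mean_silhouette, clustering.centroids
        )
        aug = _oversample(
            G_tr, C_tr, sub_cluster,
            max_neighbors=config.max_neighbors, n_bins=config.n_bins,
            rng=np.random.default_rng(config.seed), target=config.balancing_target,
            jitter_km=config.jitter_km,
        )
        aug.audit_frame().to_csv(out / "augmentation_audit.csv", index=False)
        logger.info("oversample: %d synthetic training rows", aug.n_synthetic)
        train_features = aug.doses.astype(float)
        train_lonlat = aug.lonlat
        train_coords = CoordinateSet(aug.sample_ids, aug.lonlat[:, 0], aug.lonlat[:, 1])
        if config.embedding != "none":
            raise GeolociError("[oversample] oversampling requires embedding 'none' "
                               "(synthetic genotypes are crossed in dose space)")
    else:
        train_features = F_tr.values
        train_lonlat = C_tr.lonlat
        train_coords = C_tr

    # -- optional inverse-density loss weights (over the final training rows)
    logger.info("weighted_loss: %s", "on" if config.weighted_loss else "off")
    weights_vec = None
    if config.weighted_loss:
        density = estimate_density(train_coords, config.bandwidth())
        sw = inverse_density_weights(train_coords, density, normalize=config.normalize_weights)
        sw.to_frame().to_csv(out / "sample_weights.csv", index=False)
        weights_vec = sw.weight
        logger.info("weighted_loss: weights mean %.3f, max %.3f", sw.weight.mean(), sw.weight.max())

    F_va, C_va = F_known.subset(va), C.subset(va)
    F_te, C_te = F_known.subset(te), C.subset(te)

    # -- optional hyperparameter search
    n_rows, n_cols = train_features.shape
    if config.n_trials > 0:
        space = SearchSpace(n_trials=config.n_trials, seed=config.seed)
        base = _train_config(config)
        spec, tcfg, trial_log = search_hyperparameters(
            space,
            FeatureMatrix(train_coords.sample_ids, train_features),
            train_coords, F_va, C_va, weights=weights_vec, base_config=base,
        )
        trial_log.to_csv(out / "trial_log.csv", index=False)
    else:
        spec = ModelSpec(
            input_dim=n_cols,
            n_hidden_layers=config.n_hidden_layers,
            initial_width=config.initial_width,
            resolved_width=resolve_width(config.initial_width, n_rows, n_cols),
            dropout=config.dropout,
        )
        tcfg = _train_config(config)

    # -- train
    model = GeoMLP(spec, seed=config.seed)
    fitted = train(
        model, train_features, train_lonlat, F_va.values, C_va.lonlat,
        weights=weights_vec, config=tcfg,
    )
    save_model(fitted, spec, out / "model_checkpoint.npz")

    # -- evaluate on the test partition
    test_pred = predict(fitted, F_te)
    summary = summarize_errors(test_pred, C_te, clustering.labels[te])
    pd.DataFrame(
        {
            "sample_id": test_pred.sample_ids,
            "pred_lon": test_pred.lon,
            "pred_lat": test_pred.lat,
            "true_lon": C_te.lon,
            "true_lat": C_te.lat,
            "error_km": summary.errors_km,
        }
    ).to_csv(out / "test_predictions.csv", index=False, float_format="%.8f")
    logger.info("test error: %s", summary)

    # -- predict unknowns (bootstrap when requested)
    clouds = None
    if F_unknown is not None and len(unknown_ids):
        if config.n_boot >= 2:
            results = bootstrap_predict(
                FeatureMatrix(train_coords.sample_ids, train_features),
                train_coords, F_va, C_va, F_unknown, spec, tcfg,
                n_boot=config.n_boot, seed=config.seed, weights=weights_vec,
            )
            rows = []
            clouds = {}
            for sid, res in results.items():
                clouds[sid] = res.cloud
                rows.append(
                    {
                        "sample_id": sid,
                        "lon": res.centroid[0],
                        "lat": res.centroid[1],
                        "sd_lon": res.sd_lon,
                        "sd_lat": res.sd_lat,
                        "r50_km": res.quantile_radii_km[0.5],
                        "r90_km": res.quantile_radii_km[0.9],
                        "r95_km": res.quantile_radii_km[0.95],
                    }
                )
            pd.DataFrame(rows).to_csv(
                out / "unknown_predictions.csv", index=False, float_format="%.8f"
            )
        else:
            up = predict(fitted, F_unknown)
            pd.DataFrame(
                {"sample_id": up.sample_ids, "lon": up.lon, "lat": up.lat}
            ).to_csv(out / "unknown_predictions.csv", index=False, float_format="%.8f")

    render_reports(
        out, summary=summary, history=fitted.history_frame(), prediction_clouds=clouds
    )
    return {
        "output_dir": str(out),
        "summary": summary,
        "model": fitted,
        "spec": spec,
        "split": split,
        "outlier_report": outlier_report,
    }


def _train_config(config: RunConfig) -> TrainConfig:
    return TrainConfig(
        loss_kind=config.loss_kind,
        use_weights=config.weighted_loss,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        lr_factor=config.lr_factor,
        lr_patience=config.lr_patience,
        grad_clip_norm=config.grad_clip_norm,
        huber_delta=config.huber_delta,
        seed=config.seed,
    )


def save_model(fitted: TrainedGeoModel, spec: ModelSpec, path: str | Path) -> None:
    """Write a versioned checkpoint (weights, scalers, spec, config)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "spec": asdict(spec),
        "config": asdict(fitted.config) if fitted.config else None,
    }
    state = fitted.model.state_dict()
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        feature_mean=fitted.feature_mean,
        feature_std=fitted.feature_std,
        target_mean=fitted.target_mean,
        target_std=fitted.target_std,
        **{f"state_{k}": v for k, v in state.items()},
    )


def load_model(path: str | Path) -> tuple[TrainedGeoModel, ModelSpec]:
    """Reload a checkpoint; predictions on a probe batch are bit-identical."""
    try:
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
    except Exception as exc:
        raise CheckpointError(f"cannot read checkpoint {path!r}: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {meta.get('version')} != {CHECKPOINT_VERSION}"
        )
    spec = ModelSpec(**meta["spec"])
    model = GeoMLP(spec, seed=0)
    state = {k[len("state_"):]: data[k] for k in data.files if k.startswith("state_")}
    model.load_state_dict(state)
    cfg = TrainConfig(**meta["config"]) if meta.get("config") else None
    fitted = TrainedGeoModel(
        model,
        data["feature_mean"],
        data["feature_std"],
        data["target_mean"],
        data["target_std"],
        {},
        0,
        cfg,
    )
    return fitted, spec
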