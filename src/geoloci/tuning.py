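"""Sequential hyperparameter search and SNP-resampling bootstrap.

The search follows the tree-structured Parzen estimator recipe: after a
uniform start-up phase, observed trials are split into a "good" (lowest
objective) and a "bad" fraction; one-dimensional Parzen (Gaussian-KDE)
densities l(x) and g(x) are fit per parameter over the two groups, and
each new trial picks, among candidates drawn from l, the one maximizing
l(x)/g(x) — so later trials concentrate near earlier good regions.

Geolocation uncertainty comes from a SNP-resampling bootstrap: each
pseudoreplicate resamples feature columns (loci) with replacement,
retrains the regressor from scratch with a replicate-specific seed, and
predicts every unknown sample, yielding a per-sample prediction cloud
summarized by its centroid and dispersion. Replicates depend only on
(seed, replicate index), so results are invariant to execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import CoordinateSet, FeatureMatrix
from .errors import ConfigError, DivergenceError, GeolociError
from .geometry import haversine_km
from .nn import GeoMLP, ModelSpec, TrainConfig, predict, resolve_width, train

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- search

@dataclass
class SearchSpace:
    """Ranges for the tunable model/optimization hyperparameters."""

    n_hidden_layers: tuple[int, int] = (1, 4)
    initial_width: tuple[int, int] = (32, 512)  # sampled on log scale
    learning_rate: tuple[float, float] = (1e-4, 1e-2)  # log-uniform
    dropout: tuple[float, float] = (0.0, 0.5)
    loss_kind: tuple[str, ...] = ("rmse", "huber", "drms")
    use_weights: tuple[bool, ...] = (False, True)
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")

    def as_dims(self) -> dict[str, tuple]:
        return {
            "n_hidden_layers": ("int", *self.n_hidden_layers, False),
            "initial_width": ("int", *self.initial_width, True),
            "learning_rate": ("float", *self.learning_rate, True),
            "dropout": ("float", *self.dropout, False),
            "loss_kind": ("cat", self.loss_kind),
            "use_weights": ("cat", self.use_weights),
        }


_N_STARTUP = 10
_N_CANDIDATES = 24
_GOOD_FRACTION = 0.25


def _sample_uniform(dim: tuple, rng: np.random.Generator):
    kind = dim[0]
    if kind == "cat":
        return dim[1][rng.integers(len(dim[1]))]
    _, lo, hi, log = dim
    if log:
        v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        v = float(rng.uniform(lo, hi))
    return int(round(v)) if kind == "int" else v


def _parzen_logpdf(x: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # Gaussian Parzen mixture with a flat-prior pseudo-component over the range.
    obs = np.concatenate([obs, [(lo + hi) / 2.0]])
    spread = max(obs.std(), 1e-12)
    h = max(1.06 * spread * len(obs) ** (-0.2), (hi - lo) / 50.0)
    z = (x[:, None] - obs[None, :]) / h
    dens = np.exp(-0.5 * z**2).mean(axis=1) / (h * np.sqrt(2 * np.pi))
    return np.log(np.maximum(dens, 1e-300))


def _tpe_propose(
    dims: dict[str, tuple],
    trials: list[dict],
    values: list[float],
    rng: np.random.Generator,
) -> dict:
    order = np.argsort(values, kind="stable")
    n_good = max(1, int(np.ceil(_GOOD_FRACTION * len(values))))
    good = [trials[i] for i in order[:n_good]]
    bad = [trials[i] for i in order[n_good:]] or good

    candidates = []
    scores = np.zeros(_N_CANDIDATES)
    for _ in range(_N_CANDIDATES):
        candidates.append({})
    for name, dim in dims.items():
        if dim[0] == "cat":
            choices = list(dim[1])
            gc = np.array([sum(1 for t in good if t[name] == c) + 1.0 for c in choices])
            bc = np.array([sum(1 for t in bad if t[name] == c) + 1.0 for c in choices])
            gp, bp = gc / gc.sum(), bc / bc.sum()
            picks = rng.choice(len(choices), size=_N_CANDIDATES, p=gp)
            for c, k in enumerate(picks):
                candidates[c][name] = choices[k]
            scores += np.log(gp[picks]) - np.log(bp[picks])
        else:
            _, lo, hi, log = dim
            tf = (lambda v: np.log(v)) if log else (lambda v: v)
            g_obs = np.array([tf(t[name]) for t in good], dtype=float)
            b_obs = np.array([tf(t[name]) for t in bad], dtype=float)
            tlo, thi = tf(lo), tf(hi)
            # draw candidates from the good mixture, clipped to range
            centers = g_obs[rng.integers(len(g_obs), size=_N_CANDIDATES)]
            spread = max(g_obs.std(), (thi - tlo) / 20.0)
            h = max(1.06 * spread * (len(g_obs) + 1) ** (-0.2), (thi - tlo) / 50.0)
            draws = np.clip(centers + rng.normal(0.0, h, _N_CANDIDATES), tlo, thi)
            scores += _parzen_logpdf(draws, g_obs, tlo, thi) - _parzen_logpdf(
                draws, b_obs, tlo, thi
            )
            for c, z in enumerate(draws):
                v = float(np.exp(z)) if log else float(z)
                candidates[c][name] = int(round(v)) if dim[0] == "int" else v
    return candidates[int(np.argmax(scores))]


def minimize(
    objective: Callable[[dict], float],
    dims: dict[str, tuple],
    n_trials: int,
    seed: int = 0,
) -> tuple[dict, float, pd.DataFrame]:
    """Sequential model-based minimization over a dict of parameter dims.

    ``dims`` maps name → ("int"|"float", lo, hi, log) or ("cat", choices).
    Returns (best_params, best_value, trial log).
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    values: list[float] = []
    for t in range(n_trials):
        if t < _N_STARTUP or len(values) < 2:
            params = {k: _sample_uniform(dim, rng) for k, dim in dims.items()}
        else:
            params = _tpe_propose(dims, trials, values, rng)
        val = float(objective(params))
        trials.append(params)
        values.append(val)
    log = pd.DataFrame(trials)
    log["value"] = values
    log["trial"] = np.arange(n_trials)
    finite = np.isfinite(values)
    if not finite.any():
        raise GeolociError(f"all {n_trials} trials diverged")
    best_i = int(np.flatnonzero(finite)[np.argmin(np.asarray(values)[finite])])
    return trials[best_i], values[best_i], log


def search_hyperparameters(
    space: SearchSpace,
    train_F: FeatureMatrix,
    train_C: CoordinateSet,
    val_F: FeatureMatrix,
    val_C: CoordinateSet,
    weights: np.ndarray | None = None,
    base_config: TrainConfig | None = None,
) -> tuple[ModelSpec, TrainConfig, pd.DataFrame]:
    """TPE search for the architecture/optimization hyperparameters.

    The objective is the validation mean Haversine error (km) of a model
    trained under each sampled configuration; the best trial's
    configuration is returned with the full trial log. Diverged trials
    score +inf rather than aborting the search.
    """
    base = base_config or TrainConfig()
    n_rows, n_cols = train_F.values.shape

    def objective(params: dict) -> float:
        spec = ModelSpec(
            input_dim=n_cols,
            n_hidden_layers=params["n_hidden_layers"],
            initial_width=params["initial_width"],
            resolved_width=resolve_width(params["initial_width"], n_rows, n_cols),
            dropout=params["dropout"],
        )
        cfg = TrainConfig(
            loss_kind=params["loss_kind"],
            use_weights=params["use_weights"],
            learning_rate=params["learning_rate"],
            batch_size=base.batch_size,
            max_epochs=base.max_epochs,
            patience=base.patience,
            lr_factor=base.lr_factor,
            lr_patience=base.lr_patience,
            grad_clip_norm=base.grad_clip_norm,
            seed=base.seed,
        )
        model = GeoMLP(spec, seed=base.seed)
        try:
            fitted = train(
                model, train_F.values, train_C.lonlat, val_F.values, val_C.lonlat,
                weights=weights, config=cfg,
            )
        except DivergenceError:
            return np.inf
        pred = predict(fitted, val_F)
        return float(
            np.mean(haversine_km(pred.lon, pred.lat, val_C.lon, val_C.lat))
        )

    best, best_val, log = minimize(objective, space.as_dims(), space.n_trials, space.seed)
    logger.info("search_hyperparameters: best val error %.2f km with %s", best_val, best)
    spec = ModelSpec(
        input_dim=n_cols,
        n_hidden_layers=best["n_hidden_layers"],
        initial_width=best["initial_width"],
        resolved_width=resolve_width(best["initial_width"], n_rows, n_cols),
        dropout=best["dropout"],
    )
    cfg = TrainConfig(
        loss_kind=best["loss_kind"],
        use_weights=best["use_weights"],
        learning_rate=best["learning_rate"],
        batch_size=base.batch_size,
        max_epochs=base.max_epochs,
        patience=base.patience,
        lr_factor=base.lr_factor,
        lr_patience=base.lr_patience,
        grad_clip_norm=base.grad_clip_norm,
        seed=base.seed,
    )
    return spec, cfg, log


# ------------------------------------------------------------- bootstrap

@dataclass
class PredictionResult:
    """Bootstrap prediction cloud and its aggregates for one sample."""

    sample_id: str
    cloud: np.ndarray  # n_boot × 2 lon/lat
    centroid: np.ndarray  # (lon, lat)
    sd_lon: float
    sd_lat: float
    quantile_radii_km: dict  # {0.5: r50, 0.9: r90, 0.95: r95}
    error_km: float | None = None  # centroid vs truth when known

    def covers(self, lon: float, lat: float, level: float = 0.9) -> bool:
        """Is (lon, lat) inside the cloud's ``level`` normal-quantile ellipse?"""
        cov = np.cov(self.cloud.T)
        cov += np.eye(2) * 1e-12
        diff = np.array([lon, lat]) - self.centroid
        m2 = float(diff @ np.linalg.solve(cov, diff))
        return m2 <= chi2.ppf(level, df=2)


def aggregate_bootstrap(cloud: np.ndarray, truth: tuple[float, float] | None = None,
                        sample_id: str = "") -> PredictionResult:
    """Centroid + dispersion summary of a bootstrap prediction cloud.

    Centroid is the arithmetic mean of lon/lat; dispersion is the
    per-axis SD and the 50/90/95% quantiles of Haversine distance from
    the centroid (the radii of the density contours drawn on maps).
    """
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 2 or len(cloud) == 0:
        raise GeolociError("cloud must be a non-empty n × 2 lon/lat array")
    centroid = cloud.mean(axis=0)
    d = np.asarray(
        haversine_km(cloud[:, 0], cloud[:, 1], centroid[0], centroid[1]), dtype=float
    )
    radii = {q: float(np.quantile(d, q)) for q in (0.5, 0.9, 0.95)}
    err = None
    if truth is not None:
        err = float(haversine_km(centroid[0], centroid[1], truth[0], truth[1]))
    return PredictionResult(
        sample_id,
        cloud,
        centroid,
        float(cloud[:, 0].std(ddof=1)) if len(cloud) > 1 else 0.0,
        float(cloud[:, 1].std(ddof=1)) if len(cloud) > 1 else 0.0,
        radii,
        err,
    )


def _replicate_seed(seed: int, b: int) -> int:
    return int(np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31))


def bootstrap_predict(
    train_F: FeatureMatrix,
    train_C: CoordinateSet,
    val_F: FeatureMatrix,
    val_C: CoordinateSet,
    unknown_F: FeatureMatrix,
    spec: ModelSpec,
    config: TrainConfig,
    n_boot: int = 100,
    seed: int = 0,
    weights: np.ndarray | None = None,
    truths: CoordinateSet | None = None,
) -> dict[str, PredictionResult]:
    """SNP-resampling bootstrap geolocation of the unknown samples.

    Each of the ``n_boot`` pseudoreplicates resamples feature columns
    with replacement to the original count, retrains from scratch with a
    replicate-specific seed, and predicts every unknown sample. Returns
    one :class:`PredictionResult` per unknown, with the centroid's
    Haversine error filled in when ``truths`` are supplied.
    """
    if n_boot < 2:
        raise ConfigError("n_boot must be >= 2")
    n_loci = train_F.values.shape[1]
    clouds = np.empty((n_boot, len(unknown_F.sample_ids), 2))
    for b in range(n_boot):
        s = _replicate_seed(seed, b)
        rng = np.random.default_rng(s)
        cols = rng.integers(n_loci, size=n_loci)
        rspec = ModelSpec(
            input_dim=n_loci,
            n_hidden_layers=spec.n_hidden_layers,
            initial_width=spec.initial_width,
            resolved_width=spec.resolved_width,
            dropout=spec.dropout,
        )
        rcfg = TrainConfig(**{**_config_dict(config), "seed": s})
        model = GeoMLP(rspec, seed=s)
        fitted = train(
            model,
            train_F.values[:, cols],
            train_C.lonlat,
            val_F.values[:, cols],
            val_C.lonlat,
            weights=weights,
            config=rcfg,
        )
        sub = FeatureMatrix(
            unknown_F.sample_ids, unknown_F.values[:, cols], unknown_F.provenance
        )
        pred = predict(fitted, sub)
        clouds[b] = pred.lonlat

    truth_pos = (
        {s: i for i, s in enumerate(truths.sample_ids)} if truths is not None else {}
    )
    results = {}
    for i, sid in enumerate(unknown_F.sample_ids):
        t = None
        if sid in truth_pos:
            j = truth_pos[sid]
            t = (float(truths.lon[j]), float(truths.lat[j]))
        results[sid] = aggregate_bootstrap(clouds[:, i, :], truth=t, sample_id=str(sid))
    return results


def _config_dict(cfg: TrainConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)
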