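"""YAML/CLI run configuration with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    The three mitigation toggles — ``outlier_detection``,
    ``weighted_loss``, ``oversample`` — are independent, so all eight
    on/off combinations are runnable for factorial comparisons.
    """

    # inputs / outputs
    vcf: str | None = None
    coordinates: str | None = None
    output_dir: str = "geoloci_output"
    lat_lon_order: bool = False

    # preprocessing
    mac_min: int = 2
    impute_strategy: str = "per-locus-mode"
    embedding: str = "none"  # none | pca | mds
    n_components: int = 10

    # mitigation toggles
    outlier_detection: bool = False
    weighted_loss: bool = False
    oversample: bool = False

    # mitigation parameters
    max_neighbors: int = 20
    n_bins: int = 6
    outlier_alpha: float = 0.05
    normalize_weights: bool = True
    kde_bandwidth: str = "scott"  # scott | silverman | <km float as str>
    balancing_target: str = "global-max"  # or stratum-median
    jitter_km: float = 1.0
    k_range: tuple[int, int] = (2, 10)

    # model
    n_hidden_layers: int = 2
    initial_width: int = 256
    dropout: float = 0.2
    loss_kind: str = "rmse"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 5000
    patience: int = 50
    lr_factor: float = 0.5
    lr_patience: int = 20
    grad_clip_norm: float = 1.0
    huber_delta: float = 1.0

    # splits / search / bootstrap
    split_fractions: tuple[float, float, float] = (0.75, 0.125, 0.125)
    n_trials: int = 0  # 0 disables hyperparameter search
    n_boot: int = 0  # 0 disables bootstrapping
    seed: int = 0

    # plotting
    plot_style: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mac_min < 0:
            raise ConfigError("mac_min must be >= 0")
        if not (0 <= self.outlier_alpha < 1):
            raise ConfigError("outlier_alpha must be in [0, 1)")
        fr = tuple(float(f) for f in self.split_fractions)
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigError(f"split_fractions must be 3 positive values summing to 1, got {fr}")
        self.split_fractions = fr
        self.k_range = tuple(int(k) for k in self.k_range)

    def bandwidth(self) -> str | float:
        try:
            return float(self.kde_bandwidth)
        except (TypeError, ValueError):
            return self.kde_bandwidth


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus override values.

    CLI/override values take precedence over file values; unknown keys
    in either are rejected by name.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path!r} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"bad config value: {exc}") from exc
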