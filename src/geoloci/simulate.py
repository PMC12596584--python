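"""Seed-reproducible landscape-genetic fixtures.

Simulates isolation-by-distance genotype data over a 2-D landscape:
each locus is assigned a random cline axis and a logistic allele-
frequency surface p(s) = 1/(1 + exp(−β·(proj(s) − c))), genotypes are
Binomial(2, p) draws at each sample's location, sampling locations come
from a mixture of Gaussian hotspots (biased effort) and a uniform
background, and translocations are planted by swapping the recorded
coordinates of distant sample pairs. A logistic cline is the simplest
closed-form spatial allele-frequency model and keeps fixtures fast; it
deliberately omits drift, selection, and coalescent ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, CoordinateSet, GenotypeMatrix
from .errors import ConfigError, GeolociError
from .geometry import pairwise_haversine_km, project_km, unproject_km

logger = logging.getLogger(__name__)


@dataclass
class LandscapeSim:
    """Parameters of a simulated isolation-by-distance landscape.

    The default emulates a regional study: 300 samples, 300 SNPs, a
    roughly 500-km-wide landscape, two sampling hotspots at 4:1
    relative effort holding 80% of the samples (the rest uniform
    background), and steep clines (width ~ a fifth of the landscape)
    giving a clear genotype-geography signal.

    ``local_sd`` adds spatially autocorrelated heterogeneity (random
    low-frequency cosine bumps with length scale ``local_scale_km``) to
    each locus's allele-frequency logit. Pure logistic clines are
    globally smooth, so a model trained mostly on hotspot samples still
    recovers the whole surface; real landscape-genetic data carries
    local drift structure that only local samples constrain, which is
    what makes spatially biased sampling costly. Set ``local_sd`` ~ 2
    (logit units) to emulate that regime for sampling-bias studies.
    """

    n_samples: int = 300
    n_loci: int = 300
    lon_range: tuple[float, float] = (-95.0, -90.5)  # ~400 km at 36°N
    lat_range: tuple[float, float] = (34.0, 37.6)  # ~400 km
    cline_steepness: tuple[float, float] = (0.02, 0.08)  # logistic slope per km
    hotspot_fraction: float = 0.8  # fraction of samples drawn from hotspots
    n_hotspots: int = 2
    hotspot_weights: tuple[float, ...] = (0.8, 0.2)  # relative effort per hotspot
    hotspot_sd_km: float = 30.0
    local_sd: float = 0.0  # logit-scale SD of local allele-frequency bumps
    local_scale_km: float = 60.0
    missing_rate: float = 0.0
    n_translocations: int = 0
    min_displacement_km: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lon_range[0] >= self.lon_range[1] or self.lat_range[0] >= self.lat_range[1]:
            raise ConfigError("empty landscape bounding box")
        if self.n_samples < 10 or self.n_loci < 10:
            raise ConfigError("need n_samples >= 10 and n_loci >= 10")
        if not (0.0 <= self.hotspot_fraction <= 1.0):
            raise ConfigError("hotspot_fraction must be in [0, 1]")
        if len(self.hotspot_weights) != self.n_hotspots or any(
            w <= 0 for w in self.hotspot_weights
        ):
            raise ConfigError("hotspot_weights must give a positive weight per hotspot")


def simulate_ibd(spec: LandscapeSim) -> tuple[GenotypeMatrix, CoordinateSet, pd.DataFrame]:
    """Simulate genotypes, coordinates, and a truth table from ``spec``.

    The truth table records each sample's true origin and (after
    :func:`plant_translocations`) its displaced recorded location and a
    translocation flag.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_loci

    lon0, lon1 = spec.lon_range
    lat0, lat1 = spec.lat_range
    # Sampling locations: hotspots ∪ uniform background.
    n_hot = int(round(spec.hotspot_fraction * n))
    hot_centers = np.column_stack(
        [rng.uniform(lon0, lon1, spec.n_hotspots), rng.uniform(lat0, lat1, spec.n_hotspots)]
    )
    locs = np.empty((n, 2))
    hw = np.asarray(spec.hotspot_weights, dtype=float)
    assign = rng.choice(spec.n_hotspots, size=n_hot, p=hw / hw.sum())
    hot_xy, origin = project_km(hot_centers)
    pts_xy = hot_xy[assign] + rng.normal(0.0, spec.hotspot_sd_km, size=(n_hot, 2))
    locs[:n_hot] = unproject_km(pts_xy, origin)
    locs[n_hot:, 0] = rng.uniform(lon0, lon1, n - n_hot)
    locs[n_hot:, 1] = rng.uniform(lat0, lat1, n - n_hot)
    locs[:, 0] = np.clip(locs[:, 0], lon0, lon1)
    locs[:, 1] = np.clip(locs[:, 1], lat0, lat1)

    # Logistic allele-frequency clines in projected km space.
    xy, _ = project_km(locs)
    theta = rng.uniform(0.0, 2.0 * np.pi, m)
    axes = np.column_stack([np.cos(theta), np.sin(theta)])
    beta = rng.uniform(*spec.cline_steepness, m)
    proj = xy @ axes.T  # n × m projection of each sample on each cline axis
    centers = rng.uniform(proj.min(axis=0), proj.max(axis=0))
    logit = beta * (proj - centers)
    if spec.local_sd > 0:
        # Local heterogeneity: per-locus sum of K random cosine waves with
        # wavelength ~ local_scale_km, giving spatially autocorrelated
        # deviations from the smooth cline of SD local_sd (logit units).
        K = 8
        dirs = rng.uniform(0.0, 2.0 * np.pi, (m, K))
        wavelen = spec.local_scale_km * np.exp(rng.normal(0.0, 0.3, (m, K)))
        omega = (2.0 * np.pi / wavelen)[..., None] * np.stack(
            [np.cos(dirs), np.sin(dirs)], axis=-1
        )
        phase = rng.uniform(0.0, 2.0 * np.pi, (m, K))
        amp = rng.normal(0.0, spec.local_sd / np.sqrt(K), (m, K))
        ph = np.einsum("nd,mkd->nmk", xy, omega) + phase[None]
        logit = logit + np.einsum("mk,nmk->nm", amp, np.cos(ph))
    p = 1.0 / (1.0 + np.exp(-logit))
    doses = rng.binomial(2, p).astype(np.int8)

    if spec.missing_rate > 0:
        mask = rng.random(doses.shape) < spec.missing_rate
        doses[mask] = MISSING

    ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    loci = np.array([f"snp{j:04d}" for j in range(m)], dtype=object)
    G = GenotypeMatrix(ids, loci, doses)
    C = CoordinateSet(ids, locs[:, 0], locs[:, 1])
    truth = pd.DataFrame(
        {
            "sample_id": ids,
            "true_lon": locs[:, 0],
            "true_lat": locs[:, 1],
            "recorded_lon": locs[:, 0],
            "recorded_lat": locs[:, 1],
            "translocated": np.zeros(n, dtype=bool),
        }
    )
    if spec.n_translocations:
        G, C, truth = plant_translocations(
            G, C, truth, spec.n_translocations, spec.min_displacement_km, rng
        )
    return G, C, truth


def plant_translocations(
    G: GenotypeMatrix,
    C: CoordinateSet,
    truth: pd.DataFrame,
    n: int,
    min_displacement_km: float,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, CoordinateSet, pd.DataFrame]:
    """Swap recorded coordinates of n/2 distant sample pairs (n displaced).

    Genotypes are untouched, so each displaced sample's genotype still
    points to its true origin — the geo-genetic discordance an outlier
    screen must detect. ``n`` must be even; both members of every swap
    are flagged in the truth table.
    """
    if n == 0:
        return G, C, truth
    if n % 2:
        raise ConfigError("n_translocations must be even (coordinates swap in pairs)")
    n_s = G.n_samples
    if n >= n_s / 10 + 1e-9:
        raise ConfigError("n_translocations must stay below n_samples/10")
    dist = pairwise_haversine_km(C.lonlat)
    lon = C.lon.copy()
    lat = C.lat.copy()
    truth = truth.copy()
    used: set[int] = set()
    order = rng.permutation(n_s)
    pairs: list[tuple[int, int]] = []
    for i in order:
        if len(pairs) == n // 2:
            break
        if i in used:
            continue
        cands = [j for j in np.flatnonzero(dist[i] >= min_displacement_km) if j not in used and j != i]
        if not cands:
            continue
        j = int(rng.choice(cands))
        pairs.append((int(i), j))
        used.update((int(i), j))
    if len(pairs) < n // 2:
        raise GeolociError(
            f"only {len(pairs)} eligible pairs >= {min_displacement_km} km apart"
        )
    for i, j in pairs:
        lon[i], lon[j] = lon[j], lon[i]
        lat[i], lat[j] = lat[j], lat[i]
        truth.loc[[i, j], "translocated"] = True
    truth["recorded_lon"] = lon
    truth["recorded_lat"] = lat
    logger.info("plant_translocations: swapped %d pairs (%d samples displaced)",
                len(pairs), 2 * len(pairs))
    return G, CoordinateSet(C.sample_ids, lon, lat), truth


def write_fixture(
    G: GenotypeMatrix,
    C: CoordinateSet,
    truth: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a VCF v4.2 + coordinate CSV (+ truth CSV) fixture directory.

    The VCF holds biallelic SNPs with GT fields only; the round trip
    through :func:`geoloci.io.read_vcf` / ``read_coordinates`` is
    lossless, and identical inputs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "genotypes.vcf"
    coord_path = out / "coordinates.csv"

    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(map(str, G.sample_ids)),
    ]
    for j in range(G.n_loci):
        gts = "\t".join(gt_map[int(d)] for d in G.doses[:, j])
        lines.append(f"1\t{j + 1}\t{G.loci_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    vcf_path.write_text("\n".join(lines) + "\n")

    coord_lines = ["sample_id,longitude,latitude"] + [
        f"{s},{lo:.8f},{la:.8f}" for s, lo, la in zip(C.sample_ids, C.lon, C.lat)
    ]
    coord_path.write_text("\n".join(coord_lines) + "\n")

    paths = {"vcf": vcf_path, "coordinates": coord_path}
    if truth is not None:
        truth_path = out / "truth.csv"
        truth.to_csv(truth_path, index=False, float_format="%.8f")
        paths["truth"] = truth_path
    logger.info("write_fixture: wrote %s", ", ".join(str(p) for p in paths.values()))
    return paths
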