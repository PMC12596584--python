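"""Input parsing, genotype encoding, filtering, imputation, embedding.

Reads VCF genotypes into an allele-dose matrix (via cyvcf2), parses the
sample-coordinate table, aligns the two by sample ID, applies minor
allele count filtering, imputes missing calls, and optionally embeds the
dose matrix (PCA or metric MDS) before modelling.
"""

from __future__ import annotations

import io as _io
import logging
from typing import Literal

import numpy as np
import pandas as pd

from .datatypes import MISSING, CoordinateSet, FeatureMatrix, GenotypeMatrix
from .errors import ConfigError, EmptyDataError, InputError, PairingError

logger = logging.getLogger(__name__)

ImputeStrategy = Literal["per-locus-mode", "per-locus-mean-rounded", "binomial-from-frequency"]


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a samples × loci alternate-allele dose matrix.

    Only biallelic SNP records are kept (multi-allelic and indel records
    are dropped and counted in the log). Diploid GT fields are encoded as
    alternate-allele dose 0/1/2; missing calls become the MISSING
    sentinel. Phased separators are treated like unphased ones.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise InputError(f"cannot read VCF {path!r}: {exc}") from exc

    samples = np.array(vcf.samples, dtype=object)
    if samples.size == 0:
        raise EmptyDataError(f"VCF {path!r} contains no samples")

    rows: list[np.ndarray] = []
    loci: list[str] = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    vcf.close()

    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)
    if not rows:
        raise EmptyDataError(f"VCF {path!r} has zero biallelic SNP records")

    doses = np.stack(rows, axis=1)  # variants were rows; transpose to samples × loci
    logger.info("read_vcf: %d samples × %d biallelic SNPs", doses.shape[0], doses.shape[1])
    return GenotypeMatrix(samples, np.array(loci, dtype=object), doses)


def read_coordinates(path: str, lat_lon_order: bool = False) -> CoordinateSet:
    """Parse a delimited table of sample ID, longitude, latitude.

    Comma- or tab-delimited with header auto-detection. Column order is
    sampleID, longitude, latitude by default; set ``lat_lon_order=True``
    when the file stores latitude before longitude. Rows with blank or
    "NA" coordinates are rejected with their sample IDs reported.
    """
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read coordinates {path!r}: {exc}") from exc
    if not text.strip():
        raise EmptyDataError(f"coordinate file {path!r} is empty")

    first = text.splitlines()[0]
    sep = "\t" if "\t" in first else ","
    # Header if the 2nd/3rd fields of the first line are not numeric.
    fields = [f.strip() for f in first.split(sep)]
    has_header = False
    if len(fields) >= 3:
        try:
            float(fields[1]), float(fields[2])
        except ValueError:
            has_header = True
    df = pd.read_csv(
        _io.StringIO(text),
        sep=sep,
        header=0 if has_header else None,
        dtype=str,
        skipinitialspace=True,
    )
    if df.shape[1] < 3:
        raise InputError(f"coordinate file {path!r} needs 3 columns (id, lon, lat)")
    df = df.iloc[:, :3]
    df.columns = ["sample_id", "c1", "c2"]
    if df.empty:
        raise EmptyDataError(f"coordinate file {path!r} has no data rows")

    bad = df.index[
        df["c1"].isna()
        | df["c2"].isna()
        | df["c1"].str.strip().isin(("", "NA", "na", "NaN"))
        | df["c2"].str.strip().isin(("", "NA", "na", "NaN"))
    ]
    if len(bad):
        ids = df.loc[bad, "sample_id"].tolist()
        raise InputError(f"missing coordinates for samples: {', '.join(map(str, ids[:5]))}")
    try:
        c1 = df["c1"].astype(float).to_numpy()
        c2 = df["c2"].astype(float).to_numpy()
    except ValueError as exc:
        raise InputError(f"non-numeric coordinate in {path!r}: {exc}") from exc

    lon, lat = (c2, c1) if lat_lon_order else (c1, c2)
    ids = df["sample_id"].str.strip().to_numpy(dtype=object)
    return CoordinateSet(ids, lon, lat)


def align_samples(
    G: GenotypeMatrix, C: CoordinateSet
) -> tuple[GenotypeMatrix, CoordinateSet, np.ndarray]:
    """Pair genotyped and georeferenced samples by ID.

    Returns the genotype and coordinate subsets restricted to the shared
    IDs (in the genotype matrix's order) and the IDs present only in the
    genotypes — the unknown/prediction set. Coordinates without
    genotypes are dropped with a warning.
    """
    gset = set(G.sample_ids.tolist())
    cset = set(C.sample_ids.tolist())
    shared = gset & cset
    if not shared:
        raise PairingError("genotypes and coordinates share no sample IDs")

    unknown = np.array([s for s in G.sample_ids if s not in cset], dtype=object)
    drop_c = cset - gset
    if drop_c:
        logger.warning(
            "align_samples: dropping %d coordinate rows without genotypes", len(drop_c)
        )

    keep_g = np.array([i for i, s in enumerate(G.sample_ids) if s in shared])
    Gk = G.subset_samples(keep_g)
    c_pos = {s: i for i, s in enumerate(C.sample_ids)}
    order = np.array([c_pos[s] for s in Gk.sample_ids])
    return Gk, C.subset(order), unknown


def minor_allele_counts(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor-allele count over non-missing calls."""
    d = G.doses.astype(np.int64)
    obs = d != MISSING
    alt = np.where(obs, d, 0).sum(axis=0)
    total = 2 * obs.sum(axis=0)
    return np.minimum(alt, total - alt)


def filter_minor_allele_count(G: GenotypeMatrix, mac_min: int) -> GenotypeMatrix:
    """Drop loci whose minor-allele count (over non-missing calls) < mac_min."""
    if mac_min < 0:
        raise ConfigError("mac_min must be >= 0")
    if mac_min == 0:
        return G
    keep = minor_allele_counts(G) >= mac_min
    if not keep.any():
        raise EmptyDataError(f"all loci removed at mac_min={mac_min}")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_minor_allele_count: removed %d loci (mac < %d)", n_drop, mac_min)
    return G.subset_loci(keep.nonzero()[0])


def impute_missing(
    G: GenotypeMatrix,
    strategy: ImputeStrategy = "per-locus-mode",
    seed: int | None = None,
) -> GenotypeMatrix:
    """Replace MISSING doses per locus; observed entries are never altered.

    Strategies: ``per-locus-mode`` (most frequent observed dose, ties to
    the smaller dose), ``per-locus-mean-rounded`` (observed mean rounded
    to nearest integer dose) or ``binomial-from-frequency`` (draw dose
    ~ Binomial(2, observed alt-allele frequency); seed-reproducible).
    """
    miss = G.missing_mask
    if not miss.any():
        return G
    d = G.doses.astype(np.int64)
    obs = ~miss
    n_obs = obs.sum(axis=0)
    fully_missing = (n_obs == 0).nonzero()[0]
    if fully_missing.size:
        ids = G.loci_ids[fully_missing[:5]].tolist()
        raise InputError(
            f"loci with no observed calls ({', '.join(map(str, ids))}); "
            "apply a MAC/missingness pre-filter first"
        )

    out = d.copy()
    if strategy == "per-locus-mode":
        counts = np.stack([((d == k) & obs).sum(axis=0) for k in (0, 1, 2)])
        fill = counts.argmax(axis=0)  # argmax breaks ties toward smaller dose
    elif strategy == "per-locus-mean-rounded":
        mean = np.where(obs, d, 0).sum(axis=0) / n_obs
        fill = np.clip(np.rint(mean).astype(np.int64), 0, 2)
    elif strategy == "binomial-from-frequency":
        p = np.where(obs, d, 0).sum(axis=0) / (2 * n_obs)
        rng = np.random.default_rng(seed)
        draws = rng.binomial(2, np.broadcast_to(p, d.shape))
        out[miss] = draws[miss]
        return GenotypeMatrix(G.sample_ids, G.loci_ids, out.astype(np.int8))
    else:
        raise ConfigError(f"unknown imputation strategy {strategy!r}")

    out[miss] = np.broadcast_to(fill, d.shape)[miss]
    return GenotypeMatrix(G.sample_ids, G.loci_ids, out.astype(np.int8))


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic sign convention: largest-magnitude loading positive.
    for j in range(components.shape[0]):
        k = np.argmax(np.abs(components[j]))
        if components[j, k] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return components, scores


def embed_genotypes(
    F: FeatureMatrix,
    method: Literal["none", "pca", "mds"] = "none",
    n_components: int = 10,
    seed: int | None = None,
) -> FeatureMatrix:
    """Optionally reduce the feature matrix to ``n_components`` columns.

    ``pca`` uses full-SVD principal components; ``mds`` classical
    (Torgerson) metric multidimensional scaling on Euclidean distances.
    Both fix signs so the largest-magnitude loading of each component is
    positive, making the embedding deterministic.
    """
    if method == "none":
        return F
    n, m = F.values.shape
    if not (1 <= n_components <= min(n, m)):
        raise ConfigError(
            f"n_components={n_components} out of range [1, {min(n, m)}]"
        )
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
        scores = pca.fit_transform(F.values)
        _, scores = _fix_signs(pca.components_.copy(), scores)
    elif method == "mds":
        # Classical MDS on Euclidean distances = PCA on the double-centered
        # Gram matrix; deterministic, no iterative stress majorization.
        X = F.values - F.values.mean(axis=0)
        gram = X @ X.T
        vals, vecs = np.linalg.eigh(gram)
        order = np.argsort(vals)[::-1][:n_components]
        scores = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        for j in range(scores.shape[1]):
            k = np.argmax(np.abs(scores[:, j]))
            if scores[k, j] < 0:
                scores[:, j] *= -1
    else:
        raise ConfigError(f"unknown embedding method {method!r}")
    ids = np.array([f"{method}{j + 1}" for j in range(scores.shape[1])], dtype=object)
    return FeatureMatrix(F.sample_ids, scores, provenance="embedded", feature_ids=ids)


def doses_to_features(G: GenotypeMatrix) -> FeatureMatrix:
    """View an imputed genotype matrix as a raw-dose feature matrix."""
    if G.missing_mask.any():
        raise InputError("genotype matrix still has missing calls; impute first")
    return FeatureMatrix(
        G.sample_ids, G.doses.astype(float), provenance="raw-doses", feature_ids=G.loci_ids
    )
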