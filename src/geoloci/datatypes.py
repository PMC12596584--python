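"""Core in-memory containers: genotype doses, coordinates, feature matrices.

Genotypes are stored as alternate-allele doses (0, 1, 2) in a dense
``int8`` matrix with ``MISSING`` (−9) marking uncalled genotypes.
Coordinates are decimal degrees, longitude in [−180, 180] and latitude
in [−90, 90], held in sample order matched to the genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyDataError, InputError

#: Sentinel for an uncalled genotype in a dose matrix.
MISSING: int = -9


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        uniq, counts = np.unique(ids, return_counts=True)
        dups = uniq[counts > 1]
        raise InputError(f"duplicate {what}: {', '.join(map(str, dups[:5]))}")


@dataclass
class GenotypeMatrix:
    """Samples × loci alternate-allele dose matrix.

    Attributes
    ----------
    sample_ids : np.ndarray of str, shape (n_samples,)
    loci_ids : np.ndarray of str, shape (n_loci,)
    doses : np.ndarray of int8, shape (n_samples, n_loci)
        Entries in {0, 1, 2, MISSING}.
    """

    sample_ids: np.ndarray
    loci_ids: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.loci_ids = np.asarray(self.loci_ids, dtype=object)
        self.doses = np.asarray(self.doses, dtype=np.int8)
        if self.doses.ndim != 2:
            raise InputError("doses must be a 2-D matrix")
        n, m = self.doses.shape
        if n != len(self.sample_ids):
            raise InputError("row count does not match sample_ids")
        if m != len(self.loci_ids):
            raise InputError("column count does not match loci_ids")
        if m < 1:
            raise EmptyDataError("genotype matrix has zero loci")
        _check_unique(self.sample_ids, "sample IDs")
        valid = np.isin(self.doses, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.doses[~valid])
            raise InputError(f"invalid dose values: {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return self.doses.shape[0]

    @property
    def n_loci(self) -> int:
        return self.doses.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.doses == MISSING

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids[index], self.loci_ids, self.doses[index])

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.loci_ids[index], self.doses[:, index])


@dataclass
class CoordinateSet:
    """Per-sample longitude/latitude in decimal degrees."""

    sample_ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.sample_ids) == len(self.lon) == len(self.lat)):
            raise InputError("sample_ids, lon, lat must have equal length")
        _check_unique(self.sample_ids, "sample IDs")
        if not np.isfinite(self.lon).all() or not np.isfinite(self.lat).all():
            raise InputError("coordinates must be finite")
        bad_lon = (np.abs(self.lon) > 180).nonzero()[0]
        bad_lat = (np.abs(self.lat) > 90).nonzero()[0]
        if bad_lon.size:
            i = bad_lon[0]
            raise InputError(
                f"longitude out of range for sample {self.sample_ids[i]!r}: {self.lon[i]}"
            )
        if bad_lat.size:
            i = bad_lat[0]
            raise InputError(
                f"latitude out of range for sample {self.sample_ids[i]!r}: {self.lat[i]}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def lonlat(self) -> np.ndarray:
        """n × 2 array of (lon, lat)."""
        return np.column_stack([self.lon, self.lat])

    def subset(self, index: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(self.sample_ids[index], self.lon[index], self.lat[index])


@dataclass
class FeatureMatrix:
    """Real-valued model input matrix with a provenance tag.

    ``provenance`` is "raw-doses" when the columns are (imputed) allele
    doses and "embedded" after PCA/MDS dimensionality reduction.
    """

    sample_ids: np.ndarray
    values: np.ndarray
    provenance: str = "raw-doses"
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise InputError("values must be n_samples × n_features")
        if not np.isfinite(self.values).all():
            raise InputError("feature matrix contains non-finite entries; impute first")
        if self.feature_ids is None:
            self.feature_ids = np.array(
                [f"f{j}" for j in range(self.values.shape[1])], dtype=object
            )
        else:
            self.feature_ids = np.asarray(self.feature_ids, dtype=object)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, index: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.sample_ids[index], self.values[index], self.provenance, self.feature_ids
        )
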