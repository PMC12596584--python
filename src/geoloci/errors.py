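"""Exception hierarchy shared across the package."""


class GeolociError(Exception):
    """Base class for all package errors."""


class ConfigError(GeolociError):
    """Invalid configuration value or unknown key."""


class InputError(GeolociError):
    """Unreadable or malformed input file / array."""


class EmptyDataError(InputError):
    """No usable records remain after parsing or filtering."""


class PairingError(InputError):
    """Genotypes and coordinates share no sample IDs."""


class DegenerateGeometryError(GeolociError):
    """Coordinate geometry carries no spatial information (all points coincide)."""


class DegenerateDistributionError(GeolociError):
    """An error distribution is constant and cannot be fit."""


class TooFewSamplesError(GeolociError):
    """Pruning or filtering would leave too few training samples."""


class AugmentationError(GeolociError):
    """Synthetic oversampling cannot proceed (e.g. all clusters singletons)."""


class DivergenceError(GeolociError):
    """Training produced a non-finite loss."""


class CheckpointError(GeolociError):
    """Model checkpoint is corrupted or has an incompatible version."""
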