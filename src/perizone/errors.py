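"""Exception types shared across the pipeline."""


class PerizoneError(Exception):
    """Base class for all package errors."""


class IdentifiabilityError(PerizoneError):
    """Acquisition scheme cannot support the requested model fit."""


class DegenerateGeometryError(PerizoneError):
    """Phantom geometry produces an empty or unusable region."""


class InvalidProfileError(PerizoneError):
    """Microstructure profile violates physical constraints."""


class InvalidNoiseError(PerizoneError):
    """Noise specification is not physically meaningful."""


class DegenerateParcellationError(PerizoneError):
    """Zonation cannot proceed (e.g. all edema voxels excluded)."""


class InsufficientDataError(PerizoneError):
    """Too few subjects/observations for the requested statistical test."""


class ConfigError(PerizoneError):
    """Run configuration is invalid."""
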