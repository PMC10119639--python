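"""Exception hierarchy shared across the pipeline stages."""


class GenomedynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GenomedynError, ValueError):
    """A file on disk does not conform to its declared format."""


class ValidationError(GenomedynError, ValueError):
    """An in-memory record violates a domain invariant."""


class CapacityError(GenomedynError, ValueError):
    """A simulation request cannot be packed into the space it was given."""


class EstimationError(GenomedynError, ValueError):
    """An estimator cannot produce a value from the data it was handed."""


class SaturationError(GenomedynError, ValueError):
    """A divergence is beyond the range a substitution model can correct."""


class ConfigError(GenomedynError, ValueError):
    """A run configuration is incomplete or inconsistent."""
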