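"""Exception hierarchy.

Everything derives from :class:`CountfluxError`, itself a ``ValueError``,
so callers can catch broadly without importing this module.
"""


class CountfluxError(ValueError):
    """Base class for all countflux errors."""


class SchemaError(CountfluxError):
    """A required column or config key is missing or has the wrong type."""


class ValidationError(CountfluxError):
    """Data violate an invariant (negative counts, year gaps, duplicates)."""


class CoverageError(CountfluxError):
    """A requested time window is not fully covered by the data."""


class ConfigError(CountfluxError):
    """An MCMC or pipeline configuration is internally inconsistent."""


class InitializationError(CountfluxError):
    """The sampler could not find a finite starting density."""


class DegenerateChainError(CountfluxError):
    """A chain segment has zero variance; diagnostics are undefined."""
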