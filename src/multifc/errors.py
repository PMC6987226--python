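"""Exception hierarchy shared across the package."""


class MultiFCError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MultiFCError, ValueError):
    """Input is formally valid but makes the requested quantity undefined
    (zero-variance signal, zero total mass, constant distance matrix)."""


class ContractError(MultiFCError, ValueError):
    """Caller violated an interface contract (mismatched shapes, mixed
    measures, missing subjects, single-class folds)."""


class ConfigurationError(MultiFCError, ValueError):
    """Parameter combination cannot be realised (empty frequency band at the
    achievable resolution, band outside Nyquist)."""


class EstimationError(MultiFCError, ValueError):
    """An estimator cannot produce a meaningful value from this record
    (too few averaging segments, no points outside the cone of influence)."""


class ParseError(MultiFCError, ValueError):
    """A file could not be read as the format it claims to be."""
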