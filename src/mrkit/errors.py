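"""Exception hierarchy shared across the package."""


class MRKitError(Exception):
    """Base class for all package errors."""


class ValidationError(MRKitError, ValueError):
    """A value violates a domain invariant (bad allele, SE <= 0, r2 out of range...)."""


class ConfigurationError(MRKitError, ValueError):
    """Malformed configuration or input layout (missing column, bad mapping...)."""


class InsufficientInstrumentsError(MRKitError, ValueError):
    """Too few SNPs for the requested estimator or diagnostic."""


class UndefinedRatioError(MRKitError, ZeroDivisionError):
    """A Wald ratio is undefined because the exposure effect is zero."""
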