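"""Exception hierarchy shared across fibrilkit modules."""


class FibrilkitError(Exception):
    """Base class for all fibrilkit errors."""


class InvalidParameterError(FibrilkitError, ValueError):
    """A physical parameter is outside its valid domain (e.g. R_H <= 0)."""


class NoDecayError(FibrilkitError):
    """An autocorrelation trace does not decay and cannot be inverted."""


class ConvergenceError(FibrilkitError):
    """A nonlinear fit failed to converge; the message carries diagnostics."""


class NotDeterminedError(FibrilkitError):
    """A quantity could not be determined from the supplied data."""


class SchemaError(FibrilkitError, ValueError):
    """A tabular input file does not match its expected schema."""
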