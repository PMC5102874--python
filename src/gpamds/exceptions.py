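"""Exception and warning types used across the package."""


class GpamdsError(Exception):
    """Base class for package errors."""


class FormatError(GpamdsError, ValueError):
    """Input file does not have the expected layout (e.g. missing column)."""


class ValidationError(GpamdsError, ValueError):
    """Input data violates an invariant (range, duplicates, emptiness)."""


class DesignError(GpamdsError, ValueError):
    """A simulation design is inconsistent or unsatisfiable."""


class DegenerateDataError(GpamdsError, ValueError):
    """Data degenerate for an estimator (e.g. all responsibility on p = 1)."""


class ConvergenceWarning(UserWarning):
    """EM did not reach the convergence tolerance within ``max_iter``."""
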