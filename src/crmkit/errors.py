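"""Exception types shared across the package."""


class CRMError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(CRMError, ValueError):
    """A design parameter or parameter combination is invalid."""


class InvalidStateError(CRMError, ValueError):
    """Accumulated trial data violate a structural constraint."""


class NumericalError(CRMError, ArithmeticError):
    """A posterior integral or quantile computation failed to be finite."""
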