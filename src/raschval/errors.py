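"""Exception hierarchy shared across the package."""


class RaschvalError(Exception):
    """Base class for all package errors."""


class ValidationError(RaschvalError):
    """Input data or configuration violates a contract (bad cells, labels, sizes)."""


class EstimationError(RaschvalError):
    """A numeric procedure cannot produce a result (inestimable item, non-convergence)."""
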