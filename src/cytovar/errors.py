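"""Exception types shared across the package."""


class CytovarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CytovarError):
    """A required column is missing or misnamed in an input table."""


class ValidationError(CytovarError):
    """Input data violate a contract (non-positive sizes, >2 factor levels, ...)."""


class DegenerateDesignError(CytovarError):
    """A requested design matrix would contain a constant or collinear column."""


class SingularFitError(CytovarError):
    """The least-squares problem is rank deficient."""


class ContractError(CytovarError):
    """Two objects that must share a model form / coding do not."""


class ConvergenceError(CytovarError):
    """An iterative solver hit its iteration cap before reaching tolerance."""
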