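"""Exception types shared across the package."""


class MossyInfoError(Exception):
    """Base class for all package errors."""


class ParameterError(MossyInfoError, ValueError):
    """A model or quadrature parameter is outside its legal range."""


class InvalidInputError(MossyInfoError, ValueError):
    """Runtime input (position, bin index, array shape) is invalid."""


class ConvergenceError(MossyInfoError, RuntimeError):
    """An iterative procedure (threshold search, quadrature) failed to converge."""


class UndefinedSparsityError(MossyInfoError, ArithmeticError):
    """Population sparsity is undefined (all rates zero)."""


class FitError(MossyInfoError, RuntimeError):
    """Curve fitting did not converge."""
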