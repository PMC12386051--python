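"""Exception hierarchy shared across the package."""


class CausalemError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CausalemError, ValueError):
    """Malformed or inconsistent user input (labels, shapes, parameter ranges)."""


class FormatError(InvalidInputError):
    """A file violated the expected on-disk format."""


class DegenerateCounterfactualError(CausalemError):
    """The counterfactual distribution has no mass: P_C(excluded) = 1."""


class NumericalFailureError(CausalemError):
    """An iterative routine failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual={residual:.3e})")
        self.residual = residual


class InapplicableMeasureError(CausalemError):
    """The requested measure is undefined on this state space (e.g. a
    Hamming-based measure on a space without suitable binary labels)."""
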