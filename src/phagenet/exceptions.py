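"""Exception and warning types shared across the package."""


class PhagenetError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(PhagenetError, ValueError):
    """Shapes of matrices, vectors or states do not agree."""


class FeasibilityError(PhagenetError, ValueError):
    """A parameter set cannot support a positive coexistence equilibrium."""


class FormatError(PhagenetError, ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrationError(PhagenetError, RuntimeError):
    """The ODE integrator failed to produce a valid trajectory."""


class ConditioningWarning(UserWarning):
    """The regression system is ill-conditioned or underdetermined."""
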