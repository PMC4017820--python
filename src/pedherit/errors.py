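"""Exception hierarchy for pedherit."""


class PedheritError(Exception):
    """Base class for all pedherit errors."""


class PedigreeValidationError(PedheritError, ValueError):
    """Raised when a pedigree violates structural invariants."""


class UnsupportedFeatureError(PedheritError, NotImplementedError):
    """Raised for model features deliberately out of scope (e.g. dominance)."""


class ConfigError(PedheritError, ValueError):
    """Raised for invalid scenario / MCMC / pipeline configuration."""


class NumericalError(PedheritError, ArithmeticError):
    """Raised when a linear-algebra step fails (e.g. Cholesky of a non-PD matrix)."""
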