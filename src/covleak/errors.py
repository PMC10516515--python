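"""Exception hierarchy for the federation testbed and attack modules."""


class CovleakError(Exception):
    """Base class for all package-specific errors."""


class DisclosureRefused(CovleakError):
    """A server-side disclosure check (minimum sample size or minimum
    dichotomous level count) rejected the query before any value was
    computed or released."""


class UnknownVariable(CovleakError, KeyError):
    """The referenced column or broadcast vector does not exist on the server."""


class LengthMismatch(CovleakError, ValueError):
    """Two vectors passed to a bivariate endpoint have different lengths."""


class ShapeMismatch(CovleakError, ValueError):
    """A broadcast matrix does not have one row per server observation."""


class DegenerateProbe(CovleakError, ValueError):
    """A probe vector has zero sample variance, so no regression
    coefficient (and hence no covariance) can be recovered from it."""


class ProbeDegenerate(CovleakError, RuntimeError):
    """Probe generation failed to produce a numerically full-rank matrix
    within the bounded number of redraws."""


class SingularProbe(CovleakError, RuntimeError):
    """The probe matrix is numerically rank deficient at solve time."""


class BudgetExhausted(CovleakError):
    """Answering the query would push cumulative privacy loss above the
    accountant's total budget; the answer is withheld."""


class InvalidParameter(CovleakError, ValueError):
    """A numeric parameter is outside its admissible range."""


class SpecInvalid(CovleakError, ValueError):
    """A federation specification fails validation."""


class FormatError(CovleakError, ValueError):
    """An input file does not have the expected layout or headers."""


class ConfigError(CovleakError, ValueError):
    """A run configuration file could not be parsed or validated."""
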