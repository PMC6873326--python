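"""Exception hierarchy for colsim.

Every failure mode raised by the library derives from :class:`ColsimError`
so callers can catch simulator problems without masking programming errors.
"""


class ColsimError(Exception):
    """Base class for all colsim errors."""


class ConfigurationError(ColsimError):
    """A template, state vector or run configuration is inconsistent."""


class DegenerateGateError(ColsimError):
    """Both rate functions of a gate evaluate to zero (alpha + beta == 0)."""


class OrderingError(ColsimError):
    """A compartment tree is not in Hines order (parent index >= child)."""


class SingularSystemError(ColsimError):
    """A zero pivot was encountered while eliminating the tree system."""


class NumericDivergenceError(ColsimError):
    """NaN or Inf appeared in the solver state; names the first bad compartment."""


class PartitioningError(ColsimError):
    """Microcolumn count does not match ranks x columns-per-rank."""


class RoutingError(ColsimError):
    """A spike references a gid that no rank owns."""


class SchedulingError(ColsimError):
    """A delivery queue held an entry already past due."""


class ProximityError(ColsimError):
    """The LFP electrode is (numerically) inside a compartment."""


class AlignmentError(ColsimError):
    """Two traces of different length or step size were combined."""


class ParameterError(ColsimError):
    """A stimulus or benchmark parameter is out of range."""


class FitError(ColsimError):
    """A least-squares fit is underdetermined (zero variance in x)."""
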