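"""Exception hierarchy for lineage analyses.

All package-specific failures derive from :class:`LineageVarError` so callers
can catch one base class at pipeline boundaries.
"""


class LineageVarError(Exception):
    """Base class for all lineagevar errors."""


class StructuralError(LineageVarError):
    """The parent/child structure of a lineage forest is invalid."""


class FormatError(LineageVarError):
    """A tracking table violates the dialect (columns, ordering, emptiness)."""


class EstimationError(LineageVarError):
    """Too little data for an estimator (growth rate, CV, correlation)."""


class AlignmentError(LineageVarError):
    """Two per-cell time series do not share a usable common time grid."""


class DomainError(LineageVarError):
    """An argument is outside the mathematical domain of an operation."""


class TestError(LineageVarError):
    """A statistical test cannot be formed (degenerate groups)."""


class RandomizationError(LineageVarError):
    """A randomization procedure has no eligible moves."""


class FitError(LineageVarError):
    """An iterative or regression fit failed or did not converge."""


class SimulationError(LineageVarError):
    """The stochastic lineage simulator reached an invalid state."""
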