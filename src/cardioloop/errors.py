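"""Exception hierarchy for cardioloop.

Every stage raises a subclass of :class:`CardioloopError` so that the CLI can
map any failure to a one-line diagnostic and a nonzero exit code.
"""


class CardioloopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardioloopError):
    """Invalid or inconsistent run configuration."""


class MeshError(CardioloopError):
    """Tangled grid, non-positive cell volume, or broken connectivity."""


class KinematicsError(CardioloopError):
    """Invalid deformation state (non-positive Jacobian, stretch <= 0)."""


class StabilityError(CardioloopError):
    """Time integration left its stability region (advises a smaller step)."""


class SolverError(CardioloopError):
    """Linear or nonlinear solve failed to converge, or state diverged."""


class FormatError(CardioloopError):
    """Malformed exchange file (missing column, duplicate key, gap)."""


class ComparisonError(CardioloopError):
    """Two results cannot be compared (mismatched grids or time axes)."""
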