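"""Exception hierarchy for the interface-classification pipeline.

Every error that can surface to a CLI user has a distinct type so the
command-line front end can map it to a distinct exit code.
"""


class GnmifaceError(Exception):
    """Base class for all package errors."""


class ParseError(GnmifaceError):
    """Structure input could not be parsed (malformed PDB records)."""


class EmptyStructure(GnmifaceError):
    """No C-alpha atoms found in the requested model."""


class PartitionError(GnmifaceError):
    """Subunit partition is missing, inconsistent, or names absent chains."""


class FixtureError(GnmifaceError):
    """Synthetic fixture parameters produce a degenerate geometry."""


class SingularNetworkError(GnmifaceError):
    """The residue contact network is disconnected (two or more zero modes).

    This reproduces the documented failure mode of the method: when the
    minimum inter-subunit C-alpha distance exceeds the contact cutoff the
    Kirchhoff (connectivity) matrix is singular beyond its single trivial
    zero mode and no internal-motion covariance can be defined for the
    complex as a whole.
    """


class ModeSetError(GnmifaceError):
    """A requested mode or mode set is empty or refers to a zero mode."""


class DegenerateFluctuationError(GnmifaceError):
    """A residue has (numerically) zero mean-square fluctuation, so the
    normalized cross-correlation is undefined for it."""


class CalibrationError(GnmifaceError):
    """Threshold calibration needs at least one example of each class."""


class FetchError(GnmifaceError):
    """A structure could not be retrieved from the remote archive."""
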