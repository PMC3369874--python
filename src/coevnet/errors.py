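"""Exception hierarchy for coevnet.

All package-specific failures derive from :class:`CoevnetError` so callers can
catch one base class at pipeline boundaries.
"""


class CoevnetError(Exception):
    """Base class for all coevnet errors."""


class AlignmentShapeError(CoevnetError):
    """Aligned sequences do not all share the same length."""


class EmptyInputError(CoevnetError):
    """An input file or container held no usable records."""


class UndefinedIdentityError(CoevnetError):
    """Two aligned sequences share no mutually non-gapped columns."""


class MissingReferenceError(CoevnetError):
    """The requested reference sequence id is absent from the alignment."""


class UndefinedEntropyError(CoevnetError):
    """Entropy requested for a column (or column pair) with no residues."""


class DegenerateScaleError(CoevnetError):
    """A local scale factor of zero in nearest-neighbor distance normalization."""


class InsufficientDataError(CoevnetError):
    """Not enough sequences to run the requested resampling protocol."""


class ConfigError(CoevnetError):
    """An invalid parameter combination (e.g. odd subset size)."""


class ZeroVarianceError(CoevnetError):
    """A column-pair variance of zero makes the bivariate Z-score undefined."""


class DegenerateHistogramError(CoevnetError):
    """No joint-identity cell survives the frequency floor."""


class MissingChainError(CoevnetError):
    """The requested chain is absent from the structure file."""


class MissingResidueError(CoevnetError):
    """A residue number is not resolved in the structure model."""


class UndefinedAccuracyError(CoevnetError):
    """No coupling could be resolved on the structure."""


class FitError(CoevnetError):
    """Nonlinear least-squares fit failed or is unidentifiable."""
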