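"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SupercellError`, so callers (and the CLI) can catch one type.
"""


class SupercellError(Exception):
    """Base class for all supercells errors."""


class ParseError(SupercellError):
    """A table could not be parsed (empty file, non-numeric cell, ...)."""


class SchemaError(SupercellError):
    """Column/measurement names do not match what an operation expects."""


class LabelingError(SupercellError):
    """A sample has no class label, or a label outside the cohort classes."""


class EmptyGateError(SupercellError):
    """A gating sequence removed every cell of a sample."""


class InsufficientCellsError(SupercellError):
    """A sample has too few cells for the requested supercell size."""


class DegenerateLabelsError(SupercellError):
    """A classifier was asked to fit points that carry fewer than two classes."""


class DegenerateFoldError(SupercellError):
    """A jackknife fold lost one of the two classes."""


class UndefinedRatioError(SupercellError):
    """A width ratio was requested for a measurement with zero spread."""
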