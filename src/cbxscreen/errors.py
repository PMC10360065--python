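"""Exception hierarchy for the screening pipeline.

Every error raised on a contract violation derives from
:class:`CbxScreenError` so callers can catch pipeline errors as a family
while still distinguishing ingestion problems from analysis problems.
"""


class CbxScreenError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(CbxScreenError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class PlateFormatError(CbxScreenError, ValueError):
    """A tabular input file is missing required columns or is malformed."""


class IngestionError(CbxScreenError, ValueError):
    """A plate file parsed, but a well's (time, wavelength) grid is incomplete."""


class LayoutError(CbxScreenError, ValueError):
    """A well present in the plate data has no entry in the layout."""


class NoSignalError(CbxScreenError, ValueError):
    """A spectral series is perfectly flat; no responsive wavelength exists."""


class AlignmentError(CbxScreenError, ValueError):
    """Two series that must share a grid (sample vs blank) do not."""


class DivisionGuardError(CbxScreenError, ZeroDivisionError):
    """A relative difference was requested against a nonpositive baseline."""


class FormulaParseError(CbxScreenError, ValueError):
    """A molecular formula string could not be parsed.

    Carries ``offset``, the character position of the offending token.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UndefinedCorrelationError(CbxScreenError, ValueError):
    """A correlation was requested on data with a constant coordinate."""
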