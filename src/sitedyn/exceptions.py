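"""Exception hierarchy.

Every error raised by the library subclasses :class:`SiteDynError`, so callers
(and the CLI) can catch one type. Individual classes also subclass the
closest builtin so generic handling keeps working.
"""


class SiteDynError(Exception):
    """Base class for all sitedyn errors."""


class PDBParseError(SiteDynError, ValueError):
    """A fixed-column PDB record could not be parsed.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(SiteDynError, ValueError):
    """Input file or array contains no usable records."""


class CongruenceError(SiteDynError, ValueError):
    """Coordinate sets that must correspond atom-by-atom do not."""


class SelectionError(SiteDynError, ValueError):
    """An atom selection resolved to the wrong number of atoms."""


class DegeneracyError(SiteDynError, ValueError):
    """Point sets too small or collinear for a unique rigid superposition."""


class ParameterError(SiteDynError, ValueError):
    """A numeric parameter is outside its valid range."""


class ExtractionError(SiteDynError, ValueError):
    """A required atom is missing when extracting bond vectors."""


class PairingError(SiteDynError, ValueError):
    """Two result sets cannot be matched residue-by-residue."""


class GeometryError(SiteDynError, ValueError):
    """Degenerate geometry (e.g. coincident donor and hydrogen)."""


class MissingAtomError(SiteDynError, KeyError):
    """A named atom does not exist in the structure."""
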