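"""Exception hierarchy for the adams package."""


class AdamsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AdamsError):
    """A structure file could not be parsed as PDB or mmCIF."""


class ChainNotFoundError(AdamsError):
    """The requested chain is absent from the structure."""


class EmptyTraceError(AdamsError):
    """The selected chain contains no Calpha atoms."""


class InvalidInputError(AdamsError):
    """An in-memory input violates a documented precondition."""


class DegenerateInputError(AdamsError):
    """Input is structurally valid but too small for the operation."""


class ParameterError(AdamsError):
    """A tunable parameter is outside its documented range."""


class EmptyDatabaseError(AdamsError):
    """No structure in the input collection produced a database entry."""


class GenerationError(AdamsError):
    """A synthetic-structure generator failed to satisfy its constraints."""
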