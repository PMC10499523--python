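"""Exception types shared across the pipeline."""


class SpliceAtlasError(Exception):
    """Base class for all package errors."""


class ParseError(SpliceAtlasError, ValueError):
    """A malformed input file or line."""


class MetadataError(SpliceAtlasError, KeyError):
    """A sample or junction is missing required metadata."""


class ContractError(SpliceAtlasError, ValueError):
    """A precondition of an operation was violated."""


class DegenerateInputError(SpliceAtlasError, ValueError):
    """Input carries no information for the requested computation."""
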