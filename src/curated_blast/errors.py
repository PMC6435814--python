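"""Named exceptions shared across the pipeline."""


class CuratedBlastError(Exception):
    """Base class for all errors raised by this package."""


class UnknownSourceError(CuratedBlastError):
    """A curated entry is tagged with a source database we do not know."""


class DatabaseLoadError(CuratedBlastError):
    """A saved curated database could not be read back completely."""


class InvalidQueryError(CuratedBlastError):
    """The text query is empty or degenerate (e.g. consists only of '%')."""


class InvalidSequenceError(CuratedBlastError):
    """A sequence contains characters outside the accepted alphabet."""


class DuplicateIdError(CuratedBlastError):
    """Two records in one input share an identifier."""


class AlignmentEngineError(CuratedBlastError):
    """The alignment engine failed; carries the engine's diagnostics."""


class FixtureError(CuratedBlastError):
    """A synthetic-fixture request is infeasible (e.g. overlapping plants)."""
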