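"""Exception hierarchy for the vfforage pipeline.

All pipeline-specific failures derive from :class:`VFForageError` so callers
can catch one base class at the CLI boundary.
"""


class VFForageError(Exception):
    """Base class for all vfforage errors."""


class ParseError(VFForageError):
    """A transcript or resource file could not be parsed."""


class ValidationError(VFForageError):
    """An in-memory object violates one of its invariants."""


class EmptySequenceError(VFForageError):
    """An operation required at least one animal token and found none."""


class DegenerateThresholdError(VFForageError):
    """All adjacent similarities are identical; the adaptive threshold is
    undefined and the caller should fall back to a single cluster."""


class MissingEmbeddingError(VFForageError, KeyError):
    """A word has no vector in the embedding store."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message
        return Exception.__str__(self)


class UndefinedMetricError(VFForageError):
    """A metric (AUC, cosine similarity, KS) is undefined for the input."""
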