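"""Exception hierarchy for the emgmotion package.

Every error raised by the library derives from :class:`EmgError`, so callers
can catch one base class at pipeline boundaries while tests distinguish the
failure category.
"""


class EmgError(Exception):
    """Base class for all emgmotion errors."""


class FormatError(EmgError):
    """A file or table does not have the expected structure (missing field,
    duplicate column, refusal to write a degenerate object)."""


class AlignmentError(EmgError):
    """Per-sample vectors disagree in length with the signal matrix."""


class DataError(EmgError):
    """Signal content is invalid (non-finite values)."""


class ConfigError(EmgError):
    """A configuration object violates its invariants."""


class InputError(EmgError):
    """An operation received arguments outside its precondition."""
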