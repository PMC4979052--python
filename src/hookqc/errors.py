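"""Exception hierarchy.

All package-level failures derive from :class:`HookQCError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class HookQCError(Exception):
    """Base class for all hookqc errors."""


class FormatError(HookQCError):
    """A file does not have the expected structure (header, columns)."""


class ValidationError(HookQCError):
    """Structurally parseable input violates a content invariant."""


class InsufficientDataError(HookQCError):
    """An operation refuses to run because the input is too small for a
    reliable estimate (e.g. too few absent probes for the sequence fit)."""
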