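"""Exception hierarchy.

All loopscape-raised errors derive from :class:`LoopscapeError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class LoopscapeError(Exception):
    """Base class for all errors raised by loopscape."""


class InputError(LoopscapeError, ValueError):
    """Invalid argument values or unusable input data."""


class FormatError(LoopscapeError, ValueError):
    """A file exists but violates the expected on-disk format."""


class SelectionError(LoopscapeError, ValueError):
    """An atom selection resolved to nothing or is otherwise invalid."""
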