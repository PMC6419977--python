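"""Exception hierarchy for the pipeline.

All errors derive from :class:`MyofuseError` so callers (notably batch mode)
can catch pipeline failures without swallowing programming errors.
"""


class MyofuseError(Exception):
    """Base class for all errors raised by myofuse."""


class InputError(MyofuseError):
    """A required input file or directory is missing or unreadable."""


class FormatError(MyofuseError):
    """The input file exists but is not a supported image format."""


class UnsupportedChannelCountError(FormatError):
    """The image does not have 2 or 3 channels."""


class ParameterError(MyofuseError, ValueError):
    """An analysis parameter is out of range or inconsistent."""


class ConsistencyError(MyofuseError):
    """Two inputs that must describe the same image do not match."""


class GenerationError(MyofuseError):
    """The synthetic-image generator could not satisfy its constraints."""
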