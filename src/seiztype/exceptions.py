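"""Exception hierarchy.

All package errors derive from :class:`SeizTypeError` so callers can catch
one base class; each subclass also derives from the builtin exception a
naive caller would expect (``ValueError``, ``KeyError``).
"""


class SeizTypeError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(SeizTypeError, ValueError):
    """An argument violates a documented precondition."""


class ShortSegmentError(SeizTypeError, ValueError):
    """A signal segment is shorter than the requested analysis window."""


class MissingChannelError(SeizTypeError, KeyError):
    """A channel named in the manifest is absent from the record."""


class FormatError(SeizTypeError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DegenerateWindowError(SeizTypeError, ValueError):
    """A window has zero variance (or a spectrum has a single support bin),
    so standardized moments are undefined."""


class FeatureExtractionError(SeizTypeError, ValueError):
    """No usable window survived feature extraction for a segment."""
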