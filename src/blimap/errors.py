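"""Exception hierarchy.

All package errors derive from :class:`BlimapError` so callers can catch one
base type; subclasses additionally derive from the closest builtin so that
idiomatic ``except ValueError`` / ``except KeyError`` code keeps working.
"""


class BlimapError(Exception):
    """Base class for all errors raised by blimap."""


class DesignError(BlimapError, ValueError):
    """Invalid assay or simulation design (non-positive duration, bad weights, ...)."""


class FormatError(BlimapError, ValueError):
    """Malformed plate file or table (missing column, non-monotonic time, ...)."""


class ReferenceMissingError(BlimapError, LookupError):
    """A reference trace required for double-reference subtraction is absent."""


class InterpolationRangeError(BlimapError, ValueError):
    """Reference time grid does not cover the sample grid."""


class StepLookupError(BlimapError, KeyError):
    """Requested assay step is not present in the sensorgram."""


class WindowError(BlimapError, ValueError):
    """Averaging window is longer than the step it is applied to."""


class AlphabetError(BlimapError, ValueError):
    """Sequence contains a non-standard amino-acid letter."""


class DesignMismatchError(BlimapError, ValueError):
    """Paired experiment arms disagree on ligand identity or concentration."""
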