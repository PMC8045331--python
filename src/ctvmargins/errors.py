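"""Exception hierarchy.

All package errors derive from :class:`CtvMarginsError` so callers can catch
everything with one clause; most also subclass the closest builtin
(``ValueError`` for bad inputs) so idiomatic handling keeps working.
"""


class CtvMarginsError(Exception):
    """Base class for all errors raised by this package."""


class GeometryMismatchError(CtvMarginsError, ValueError):
    """Two volumes do not share shape, spacing, origin and axis directions."""


class EmptyVolumeError(CtvMarginsError, ValueError):
    """An operation requiring foreground voxels got an all-background mask."""


class DegenerateContourError(CtvMarginsError, ValueError):
    """A planar contour has fewer than three vertices."""


class LabelParseError(CtvMarginsError, ValueError):
    """A direction label contains unknown or contradictory anatomical tokens."""


class CastError(CtvMarginsError, RuntimeError):
    """A ray could not be resolved (never exits a mask within the grid cap)."""


class NoVectorError(CtvMarginsError, RuntimeError):
    """No expansion vector was accepted for a direction."""


class InsufficientExpertsError(CtvMarginsError, ValueError):
    """Fewer than two expert contours where a spread statistic is requested."""


class NoRatersError(CtvMarginsError, ValueError):
    """STAPLE called with an empty rater list."""


class DegenerateInputError(CtvMarginsError, ValueError):
    """STAPLE called with all-background rater masks."""


class ClearanceError(CtvMarginsError, ValueError):
    """A phantom's expanded target volume would not fit inside its grid."""


class StudyConfigError(CtvMarginsError, ValueError):
    """A study configuration file is malformed."""


class FewVectorsWarning(UserWarning):
    """A directional margin was computed from very few accepted vectors."""
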