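"""Exception hierarchy for famap.

All famap errors derive from :class:`FamapError` so callers can catch the
package's failures with a single except clause while still distinguishing
geometry problems from degenerate statistical input.
"""


class FamapError(Exception):
    """Base class for all famap errors."""


class FormatError(FamapError):
    """A file could not be parsed as the expected on-disk format."""


class GeometryError(FamapError):
    """Volumes or streamlines disagree in shape or affine."""


class DimensionError(FamapError):
    """Array lengths or shapes are inconsistent with each other."""


class DegenerateInputError(FamapError):
    """Statistically degenerate input (empty mask, constant scores, ...)."""


class ParameterError(FamapError):
    """A parameter is outside its valid range."""


class DataError(FamapError):
    """Input data contain non-finite or otherwise invalid values."""
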