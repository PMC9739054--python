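"""Exception hierarchy shared across the pipeline.

Every error raised on purpose derives from :class:`WheatScreenError` so the
CLI can map failures to a named error class and a nonzero exit code.
"""


class WheatScreenError(Exception):
    """Base class for all wheatscreen errors."""


class FormatError(WheatScreenError):
    """A file on disk does not match the expected layout."""


class DesignViolationError(WheatScreenError):
    """The field book breaks the augmented-design structure."""


class IncompleteDesignError(DesignViolationError):
    """A block is missing a check observation needed for adjustment."""


class ParameterError(WheatScreenError, ValueError):
    """An invalid parameter value was supplied."""


class DegenerateSampleError(WheatScreenError):
    """A physiological sample has a zero or inverted denominator."""


class SegmentationError(WheatScreenError):
    """Canopy segmentation failed (unimodal image or too few pixels)."""


class AnalysisError(WheatScreenError):
    """A statistical computation is undefined for the given input."""
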