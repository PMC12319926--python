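"""Exception types shared across the toolkit."""


class LinescanError(Exception):
    """Base class for all toolkit errors."""


class PulseDesignError(LinescanError):
    """The requested RF pulse specification has no feasible filter solution."""


class GeometryError(LinescanError):
    """A saturation region or motion shift falls outside the spatial grid."""


class UnboundedLineError(LinescanError):
    """A profile never drops below half maximum, so no FWHM exists."""


class DegenerateProfileError(LinescanError):
    """A profile carries no signal, so the requested metric is undefined."""


class SegmentationError(LinescanError):
    """Gray-matter border detection failed or received unusable input."""


class AlignmentError(LinescanError):
    """Shift search received an unusable (e.g. zero-variance) reference."""
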