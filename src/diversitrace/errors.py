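"""Exception hierarchy for the diversitrace pipeline."""


class DiversitraceError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(DiversitraceError, ValueError):
    """Session design violates its invariants (non-positive counts, durations...)."""


class ConfigError(DiversitraceError, ValueError):
    """Generator / pipeline configuration is inconsistent (e.g. mixing shape)."""


class RangeError(DiversitraceError, ValueError):
    """A parameter left its admissible range (e.g. narrowband fraction outside [0, 1])."""


class DegenerateSignalError(DiversitraceError, ValueError):
    """Zero-variance (constant) signal where variance is required."""


class EmptyInputError(DiversitraceError, ValueError):
    """Empty sequence passed to an operation requiring at least one symbol."""


class LengthError(DiversitraceError, ValueError):
    """Signal shorter than a filter order or otherwise too short."""


class AnnotationError(DiversitraceError, ValueError):
    """Missing or malformed condition annotations."""


class ChannelError(DiversitraceError, ValueError):
    """Required channel absent or montage/channel mismatch."""


class QualityError(DiversitraceError, ValueError):
    """Data quality below repairable limits (e.g. too many bad channels)."""


class SampleSizeError(DiversitraceError, ValueError):
    """Too few observations for the requested statistic."""


class DesignError(DiversitraceError, ValueError):
    """Incomplete repeated-measures design (missing cells/conditions)."""


class PrecisionError(DiversitraceError, ValueError):
    """Monte Carlo resolution insufficient (too few draws / permutations)."""


class ParseError(DiversitraceError, ValueError):
    """Malformed file header or missing companion file."""
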