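"""Exception hierarchy shared across the toolkit."""


class MtPopGenError(Exception):
    """Base class for all toolkit errors."""


class AlignmentError(MtPopGenError):
    """Malformed alignment (e.g. sequences of unequal length)."""


class LabelingError(MtPopGenError):
    """Taxon/group bookkeeping problem (unknown taxon, missing label)."""


class AnnotationError(MtPopGenError):
    """Region/frame annotation is missing or inconsistent."""


class GroupingError(MtPopGenError):
    """An operation that needs two groups got fewer."""


class DegenerateInputError(MtPopGenError):
    """Statistically empty input (no sites, no sequences)."""


class InsufficientSampleError(MtPopGenError):
    """Sample too small for the requested statistic."""


class SaturationError(MtPopGenError):
    """Distance correction undefined (log argument non-positive)."""


class FrameError(MtPopGenError):
    """Coding sequence length is not a multiple of three."""


class CodingError(MtPopGenError):
    """Internal stop codon or otherwise invalid coding sequence."""


class SpecError(MtPopGenError):
    """Invalid simulation specification."""


class SizeError(MtPopGenError):
    """Problem size exceeds a configured exhaustive-enumeration guard."""


class ConfigError(MtPopGenError):
    """Invalid run configuration (bad path, missing field)."""
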