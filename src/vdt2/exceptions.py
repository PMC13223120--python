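"""Exception hierarchy."""


class VDT2Error(Exception):
    """Base class for all package errors."""


class NoVoicedFramesError(VDT2Error):
    """Raised when pitch analysis finds no voiced frames in a signal."""


class InsufficientCyclesError(VDT2Error):
    """Raised when fewer glottal cycles are available than a perturbation
    measure needs (apq11 requires 11-point windows, hence >= 12 cycles)."""


class MetadataParseError(VDT2Error):
    """Raised for recording filenames that do not follow the
    ``name_M_T/N/sen_a_1.wav`` convention; carries the offending field."""


class ZeroVarianceError(VDT2Error):
    """Raised when a feature has zero variance on the training rows, which
    makes z-scoring undefined; names the feature."""


class ConfigError(VDT2Error):
    """Raised for invalid generator, model or pipeline configuration."""


class PipelineError(VDT2Error):
    """Raised when a pipeline stage fails; message names the stage."""
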