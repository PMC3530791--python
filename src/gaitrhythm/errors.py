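"""Exception types shared across the pipeline."""


class GaitRhythmError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GaitRhythmError, ValueError):
    """A parameter is outside its documented range."""


class NoTemplateError(GaitRhythmError):
    """The trace contains too little periodic content to self-template.

    Callers may fall back to the canonical synthetic step waveform.
    """


class InsufficientDataError(GaitRhythmError):
    """Not enough valid hours (or subjects) to compute the requested statistic."""


class TraceFormatError(GaitRhythmError, ValueError):
    """A delimited-text input file violates its documented schema."""
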