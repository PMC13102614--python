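"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`AdspeechError`; the CLI maps these
onto exit codes (config errors -> 2, data errors -> 3, stage failures -> 4).
"""


class AdspeechError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(AdspeechError):
    """A configuration value violates its documented range or a referenced
    resource (frequency table, corpus file) is missing."""


class DataError(AdspeechError):
    """Malformed or inconsistent input data (dimension mismatch, non-finite
    feature after imputation, unknown feature code)."""


class EmptyTranscriptError(DataError):
    """Transcript contains no word tokens after normalization."""


class EmptyInputError(DataError):
    """A window or token list required to be non-empty was empty."""


class AnnotationError(DataError):
    """The annotator failed on a span of text, or produced a label outside
    the closed POS inventory."""

    def __init__(self, message: str, span: str | None = None):
        super().__init__(message)
        self.span = span


class RegistryError(DataError):
    """A feature code is not one of the 32 registered biomarkers."""


class StratificationError(DataError):
    """A class has fewer members than the requested number of folds."""


class TractabilityError(AdspeechError):
    """Exact coalition enumeration requested for too many features."""


class StageError(AdspeechError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
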