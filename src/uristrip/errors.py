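"""Exception hierarchy.

Two top-level families matter to callers (and to the CLI exit-code scheme):
``ConfigError`` for bad user input discovered before the pipeline runs, and
``PipelineError`` for failures of the image-processing chain itself.
"""


class UristripError(Exception):
    """Base class for all package errors."""


class ConfigError(UristripError):
    """Invalid configuration, layout file, or argument schema."""


class ColorInputError(UristripError, ValueError):
    """Color value outside the accepted input domain."""


class PipelineError(UristripError):
    """A stage of the judging pipeline failed on otherwise valid input."""

    stage = "pipeline"


class RegistrationError(PipelineError):
    """Feature detection, matching, or homography estimation failed."""

    stage = "registration"


class SamplingError(PipelineError):
    """Patch sampling window invalid for the given image."""

    stage = "sampling"


class ExtractionError(PipelineError):
    """A chart patch or strip pad could not be read from the aligned image."""

    stage = "extraction"


class JudgmentError(PipelineError):
    """Grade judgment could not be performed."""

    stage = "judgment"


class EvaluationError(UristripError):
    """Evaluation statistics undefined for the given records."""
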