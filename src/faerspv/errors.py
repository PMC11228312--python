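"""Exception hierarchy shared across the pipeline stages."""


class FaersPVError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FaersPVError):
    """A configuration value is invalid; message names the offending field."""


class IngestionError(FaersPVError):
    """A mandatory input file is missing or unreadable."""


class FormatError(FaersPVError):
    """A file header or dialect element could not be interpreted."""


class ConsistencyError(FaersPVError):
    """Cross-table or cross-stage counts disagree."""


class DegenerateTableError(FaersPVError):
    """An odds ratio is undefined because a margin of the 2x2 is empty."""


class UnknownGroupError(FaersPVError, KeyError):
    """A requested simulation group does not exist in the ground truth."""


class StageError(FaersPVError):
    """A pipeline stage failed; message names the stage."""
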