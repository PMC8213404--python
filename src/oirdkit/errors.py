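"""Exception hierarchy shared across the pipeline."""


class OirdkitError(Exception):
    """Base class for all package errors."""


class FormatError(OirdkitError):
    """A file does not conform to the expected on-disk layout."""


class MetadataError(OirdkitError):
    """Required recording metadata is missing or invalid."""


class DegenerateSampleError(OirdkitError):
    """A statistical routine received a sample it cannot operate on
    (constant values, zero variance, all ties)."""


class DesignError(OirdkitError):
    """A factorial design is incomplete (empty cell, missing level)."""


class PairingError(OirdkitError):
    """An animal lacks one of the paired drug conditions."""


class InsufficientDataError(OirdkitError):
    """Fewer observations than the operation requires."""
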