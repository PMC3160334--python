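"""Exception hierarchy for the chromsig pipeline.

All pipeline stages raise subclasses of :class:`ChromsigError` so the CLI
can distinguish expected data/configuration problems (nonzero exit with a
message) from genuine bugs.
"""


class ChromsigError(Exception):
    """Base class for all chromsig errors."""


class MatrixFormatError(ChromsigError):
    """Malformed expression-matrix file (ragged rows, duplicate ids, empty)."""


class ModuleFormatError(ChromsigError):
    """Malformed gene-module (GMT) file."""


class ParameterError(ChromsigError):
    """A parameter is outside its valid domain."""


class AlignmentError(ChromsigError):
    """Two inputs that must share a sample set do not."""


class SizingError(ChromsigError):
    """A synthetic scenario asks for more module genes than the universe holds."""


class ConfigurationError(ChromsigError):
    """An invalid pipeline or qPCR configuration (e.g. missing reference gene)."""


class NormalizationError(ChromsigError):
    """Gene normalization is impossible (fewer than two samples)."""
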