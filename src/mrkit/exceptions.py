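"""Exception hierarchy.

Every error raised by mrkit derives from :class:`MrkitError`, so pipeline
callers can distinguish analysis failures from programming errors.
"""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrkitError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(MrkitError):
    """A summary-statistics table could not be parsed or lacks a mandatory column."""


class HarmonizationError(MrkitError):
    """Exposure and outcome tables could not be harmonized (e.g. no shared SNPs)."""


class InstrumentSelectionError(MrkitError):
    """No SNP survived instrument selection; callers must surface this."""


class LdMatrixError(MrkitError):
    """The LD matrix is missing an entry required for clumping."""


class EstimationError(MrkitError):
    """An estimator received an input it cannot handle (too few SNPs, rank deficiency...)."""
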