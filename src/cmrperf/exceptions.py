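"""Exception hierarchy for the perfusion pipeline.

All pipeline errors derive from :class:`CmrperfError` so callers (and the
CLI) can map them to exit codes: input/data problems exit 2, configuration
and parameter problems exit 3.
"""


class CmrperfError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(CmrperfError, ValueError):
    """A numeric parameter is non-finite or outside its documented range."""


class ConfigurationError(CmrperfError, ValueError):
    """A configuration object is inconsistent (missing state, bad YAML...)."""


class GeometryError(ConfigurationError):
    """A region or phantom geometry is empty or degenerate."""


class InputError(CmrperfError, ValueError):
    """Supplied data files or records are missing, duplicated or malformed."""


class NoEnhancementError(CmrperfError):
    """A time-intensity curve never rises above its baseline (flat curve)."""


class InsufficientRiseError(CmrperfError):
    """The rise between contrast arrival and peak is shorter than the fit window."""


class NormalizationError(CmrperfError):
    """The blood-pool up-slope is non-positive; normalization is undefined."""


class UndefinedStatisticError(CmrperfError):
    """A test statistic is undefined (e.g. zero variance in both groups)."""


class InsufficientDataError(CmrperfError):
    """Too few subjects per group for the requested summary or test."""
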