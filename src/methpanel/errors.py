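"""Exception hierarchy for methpanel.

All package errors derive from :class:`MethPanelError` so callers can catch
one base class at pipeline boundaries.
"""


class MethPanelError(Exception):
    """Base class for all methpanel errors."""


class ConfigError(MethPanelError, ValueError):
    """Invalid configuration; message names the offending field."""


class ValidationError(MethPanelError, ValueError):
    """Input table violates a structural invariant."""


class UnscorableSiteError(MethPanelError, ValueError):
    """Bisulfite trace site with no signal in either channel."""


class InsufficientStandardsError(MethPanelError, ValueError):
    """Standard curve requested with fewer than three distinct dilution levels."""


class CurveQualityError(MethPanelError, ValueError):
    """Fitted standard curve fails a sanity requirement (e.g. non-negative slope)."""


class NonQuantifiableError(MethPanelError, ValueError):
    """Reference assay yielded zero quantity; PMR undefined for the sample."""
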