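"""Exception hierarchy.

Everything raised deliberately by mrkit derives from :class:`MRError` so
callers (notably the pipeline, which isolates per-analysis failures) can
catch one type.
"""


class MRError(Exception):
    """Base class for all mrkit errors."""


class ConfigError(MRError):
    """A configuration problem: missing column role, bad analysis config."""


class ValidationError(MRError):
    """Input data violates a table or type invariant."""


class EmptySetError(MRError):
    """No SNPs survive a selection/harmonisation step; no analysis possible."""


class InsufficientInstrumentsError(MRError):
    """Fewer SNPs than the estimator's minimum (Egger/median need 3, PRESSO 4)."""


class DegenerateInstrumentError(MRError):
    """A SNP-exposure effect is exactly zero, so its Wald ratio is undefined."""


class CollinearityError(MRError):
    """Rank-deficient multivariable design; names the offending exposures."""


class UnderIdentifiedError(MRError):
    """Multivariable set has no more SNPs than exposures."""


class UnavailableResultError(MRError):
    """A quantity cannot be computed from the data supplied (e.g. missing EAF)."""


class NoCorrectedEstimateError(MRError):
    """MR-PRESSO flagged every SNP; no outlier-corrected estimate exists."""
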