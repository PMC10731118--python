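"""Exception hierarchy.

All package errors derive from :class:`MRKitError` so callers can catch one
type; configuration problems (bad thresholds, unknown scenario names) are
distinguished from input-data problems and from situations where estimation
is simply impossible (empty instrument sets, too few SNPs).
"""


class MRKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRKitError, ValueError):
    """A parameter or configuration value is invalid."""


class InputError(MRKitError, ValueError):
    """Input data violate a structural requirement (e.g. duplicate variants)."""


class DomainError(MRKitError, ValueError):
    """A numeric argument lies outside the formula's domain."""


class EstimationImpossibleError(MRKitError):
    """No estimate can be produced from the given data (e.g. empty join)."""


class InsufficientInstrumentsError(EstimationImpossibleError):
    """Fewer SNPs than the method's minimum."""


class CollinearityError(MRKitError):
    """Exposure effect matrix is rank deficient in multivariable MR."""

    def __init__(self, exposures):
        self.exposures = list(exposures)
        super().__init__(
            "exposure beta matrix is rank deficient; collinear exposures: "
            + ", ".join(self.exposures)
        )
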