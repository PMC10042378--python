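"""Exception types shared across the package."""


class GaitRiskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GaitRiskError):
    """Invalid walker or analysis configuration."""


class OutOfDomainError(GaitRiskError):
    """A walker state or perturbation lies outside the configured domain."""


class StructuralError(GaitRiskError):
    """A mesh or chain violates a structural requirement (e.g. a state with
    no outgoing transitions)."""


class NonAbsorbingChainError(GaitRiskError):
    """The transient block has spectral radius >= 1, so absorption is not
    guaranteed and first-passage statistics are undefined."""


class InsufficientDataError(GaitRiskError):
    """Too few steps / conditions for the requested statistic."""


class DegenerateGeometryError(GaitRiskError):
    """Hip and stance contact coincide; the pendulum length is zero."""


class FailedStepError(GaitRiskError):
    """A kinetic metric was requested for a step with non-positive normal
    ground reaction force."""


class SchemaError(GaitRiskError):
    """Serialized object does not match the expected schema/version."""
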