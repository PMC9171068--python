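"""Exception hierarchy for the step-clamp analysis pipeline."""


class StepClampError(Exception):
    """Base class for all package-specific errors."""


class BundleFormatError(StepClampError):
    """The sweep bundle on disk is missing required pieces (e.g. manifest)."""


class BundleCorruptionError(StepClampError):
    """The sweep table is internally inconsistent (truncated/NaN columns)."""


class UnsupportedVersionError(BundleFormatError):
    """The bundle manifest declares a format version this reader cannot parse."""


class ProtocolError(StepClampError):
    """A required sweep/amplitude is absent from the recording."""


class InsufficientBaselineError(StepClampError):
    """The pre-step epoch is too short for the requested baseline window."""


class UndefinedResponseError(StepClampError):
    """A steady-state window was entirely consumed by spikes."""


class NonSettlingError(StepClampError):
    """The voltage never crossed the 67% level within the step."""


class SimulationError(StepClampError):
    """Numerical integration diverged (non-finite state)."""


class RheobaseUnboundedError(StepClampError):
    """No spike was elicited even at the upper search bound."""


class SpecError(StepClampError):
    """A cohort/pipeline specification is unsatisfiable or malformed."""


class MetadataError(StepClampError):
    """Per-cell metadata (e.g. series resistance) is invalid."""


class DegenerateDataError(StepClampError):
    """Statistical input has no usable variance."""


class DesignError(StepClampError):
    """Group design for a comparison is invalid (missing/too-small groups)."""
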