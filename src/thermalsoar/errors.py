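"""Exception hierarchy shared across the pipeline."""


class ThermalSoarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermalSoarError):
    """Invalid configuration: missing columns, unresolvable paths, bad YAML."""


class EmptyInputError(ThermalSoarError):
    """An input contained no usable rows."""


class SegmentationContractError(ThermalSoarError):
    """A window handed to the projection/segmentation layer violates the
    31-fix / 30-s contract."""


class DomainError(ThermalSoarError, ValueError):
    """A physical quantity is outside its meaningful domain
    (non-positive speed, bank angle >= 90 deg, ...)."""


class FitError(ThermalSoarError):
    """A statistical fit could not be performed (degenerate predictor,
    insufficient altitude span, ...)."""
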