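"""Exception hierarchy shared across the toolkit."""


class FracAugError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(FracAugError):
    """An input value violates a documented precondition."""


class GeometryError(ValidationError):
    """Two volumes that must share a grid do not."""


class ConfigurationError(FracAugError):
    """A specification (phantom, cohort, run config) cannot be realised."""
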