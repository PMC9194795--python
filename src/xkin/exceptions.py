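"""Exception types shared across the pipeline."""


class XkinError(ValueError):
    """Base class for all xkin errors."""


class FormatError(XkinError):
    """A file or table does not match the expected on-disk layout."""


class ValidationError(XkinError):
    """Data violate a container invariant (shape, sign, integrality, ids)."""


class ParameterError(XkinError):
    """A parameter is outside its valid domain."""


class InsufficientDataError(XkinError):
    """Too little data to run an estimator."""
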