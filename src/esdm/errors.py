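"""Exception hierarchy shared across the pipeline stages."""


class EsdmError(Exception):
    """Base class for all package errors."""


class FormatError(EsdmError):
    """A file or table does not conform to the expected format."""


class ContractError(EsdmError):
    """An operation was called with arguments violating its preconditions."""


class CoverageError(EsdmError):
    """A source raster does not cover the requested target grid."""


class SchemaError(EsdmError):
    """A prediction stack does not provide the features a model was trained on."""


class CapacityError(EsdmError):
    """A sample was requested that exceeds the available population."""


class NoAdmissibleModelError(EsdmError):
    """Every candidate model fell below the AUC admission cutoff."""
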