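"""Exception hierarchy shared across the pipeline."""


class OpdPipeError(Exception):
    """Base class for all package errors."""


class InfeasiblePackingError(OpdPipeError):
    """Requested oocyte packing cannot be realized geometrically."""


class UndefinedVolumeFractionError(OpdPipeError):
    """Volume fraction requested with zero valid grid points."""


class ModelDomainError(OpdPipeError):
    """A model produced or received a value outside its domain."""


class SchemaError(OpdPipeError):
    """Input table violates the documented schema."""


class MissingDataError(OpdPipeError):
    """An operation lacks the rows it needs."""
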