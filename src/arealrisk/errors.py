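"""Exception types raised by the pipeline."""


class ArealRiskError(Exception):
    """Base class for all package errors."""


class SchemaError(ArealRiskError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(ArealRiskError):
    """An input table violates a data-model invariant (e.g. events > population)."""


class GeometryError(ArealRiskError):
    """Invalid, duplicated or dangling area geometry / adjacency input."""
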