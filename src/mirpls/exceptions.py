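"""Exception hierarchy.

Every exception carries a short machine-parsable ``category`` used by the
CLI to build one-line error reports and select a nonzero exit code.
"""


class MirplsError(Exception):
    """Base class for all package errors."""

    category = "error"


class ValidationError(MirplsError):
    """Input data violates an invariant (non-finite values, bad shape...)."""

    category = "validation"


class ShapeError(MirplsError):
    """Dimension mismatch between inputs."""

    category = "shape"


class ParameterError(MirplsError):
    """Hyperparameter outside its admissible range."""

    category = "parameter"


class ParseError(MirplsError):
    """A text file could not be parsed."""

    category = "parse"


class DegenerateDataError(MirplsError):
    """Data degenerate for the requested operation (constant column, ...)."""

    category = "degenerate"


class KnotPlacementError(MirplsError):
    """Too few distinct abscissa values for the requested knot count.

    Callers may catch this and retry with a smaller knot count.
    """

    category = "knots"


class ModelFileError(MirplsError):
    """A model file is truncated, tampered with or version-incompatible."""

    category = "model-file"
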