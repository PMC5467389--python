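"""Exception hierarchy shared across the package."""


class CoipQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CoipQuantError, ValueError):
    """A value violates a precondition (bad residue, nonpositive charge, ...)."""


class UndefinedRatioError(CoipQuantError, ZeroDivisionError):
    """A ratio or normalization is requested with a zero denominator."""


class DegenerateSampleError(CoipQuantError, ValueError):
    """A statistical test received a sample it cannot evaluate (e.g. zero variance)."""


class InvalidDesignError(CoipQuantError, ValueError):
    """A factorial design is unusable (empty cell, single level, ...)."""


class SchemaError(CoipQuantError, ValueError):
    """An input table does not match the expected schema; message carries context."""


class GateError(CoipQuantError, RuntimeError):
    """A quality gate (e.g. the TH lesion-validation criterion) failed."""
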