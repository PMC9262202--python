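"""Exception hierarchy.

Exit-code mapping used by the command line interface:
validation errors -> 2, degenerate-data errors -> 3, solver failures -> 4.
"""


class LpdaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(LpdaError, ValueError):
    """Invalid user input: bad shapes, non-finite values, unknown labels, ..."""


class SchemaError(ValidationError):
    """A serialized model file does not match the expected schema."""


class DegenerateDataError(LpdaError):
    """The two weighted group centroids coincide, so no discriminant
    hyperplane is guaranteed to exist at the LP optimum."""


class SolverError(LpdaError):
    """The LP backend failed or returned an unusable solution."""
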