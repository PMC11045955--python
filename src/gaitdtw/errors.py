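"""Exception hierarchy for the gait-recognition pipeline."""


class GaitDtwError(Exception):
    """Base class for all package errors."""


class SchemaError(GaitDtwError):
    """A declared channel, field or unit is missing or inconsistent."""


class FormatError(GaitDtwError):
    """A file is structurally malformed (bad CSV/JSON, non-monotonic time)."""


class DataError(GaitDtwError):
    """The data content violates a constraint (e.g. long NaN runs)."""


class ParameterError(GaitDtwError, ValueError):
    """An argument is outside its admissible range."""


class DegenerateSignalError(GaitDtwError, ValueError):
    """A signal has no usable variation (constant, zero power)."""


class IncompleteSetError(GaitDtwError):
    """A template set is missing one or more locomotion modes."""
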