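"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid user input or configuration (CLI exit code 2)."""


class MalformedTableError(ValidationError):
    """A feature table violates its format contract (negative cell, ...)."""


class DuplicateSampleError(ValidationError):
    """The same sample id appears more than once."""
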