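"""Exception hierarchy shared across the pipeline."""


class CitscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CitscreenError, ValueError):
    """A corpus file is missing required columns."""


class ValidationError(CitscreenError, ValueError):
    """A corpus violates its invariants (duplicate ids, bad labels, empty class)."""


class ParameterError(CitscreenError, ValueError):
    """A parameter is outside its documented range."""


class DegenerateInputError(CitscreenError, ValueError):
    """Input too degenerate to operate on (single class, empty vocabulary, ...)."""
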