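"""Exception hierarchy.

All package-specific failures derive from :class:`SnapogError` so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class SnapogError(Exception):
    """Base class for all errors raised by this package."""


class NewickParseError(SnapogError):
    """Malformed Newick input (unbalanced parentheses, stray tokens, ...)."""


class ValidationError(SnapogError):
    """Structurally valid input that violates a documented precondition."""


class NamingError(ValidationError):
    """A sequence/tip label does not follow the ``taxon|gene`` convention."""


class ParameterError(ValidationError):
    """An out-of-range or inconsistent user parameter."""


class UndefinedMetricError(SnapogError):
    """A metric is mathematically undefined for the given input."""
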