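"""Exception hierarchy.

All package errors derive from :class:`WextropyError`; the subclasses also
inherit from the matching builtin so generic ``except ValueError`` style
handling keeps working.
"""


class WextropyError(Exception):
    """Base class for all wextropy errors."""


class DomainError(WextropyError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class EstimationError(WextropyError, RuntimeError):
    """A data-driven estimation step failed (degenerate sample, ML failure)."""


class NumericsError(WextropyError, ArithmeticError):
    """A quadrature or other numerical routine diverged or lost accuracy."""
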