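"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (validation -> 2, no result -> 3,
solver failure -> 4), so library code should raise the most specific
class that applies.
"""


class GenoslimError(Exception):
    """Base class for all package errors."""


class ValidationError(GenoslimError, ValueError):
    """Invalid input data or parameters."""


class ParseError(GenoslimError, ValueError):
    """A file could not be parsed under the named format."""


class SolverError(GenoslimError, RuntimeError):
    """The LP/MILP backend failed for reasons other than infeasibility."""


class NoResultError(GenoslimError):
    """A search legitimately produced no result (e.g. no deletable window)."""
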