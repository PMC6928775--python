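"""Exception hierarchy shared across the package.

``InputError`` covers malformed arguments and format violations (CLI exit
code 2); ``InfeasibleSearchError`` covers searches whose feasible region is
empty or whose budget relation cannot be satisfied (CLI exit code 3).
"""


class WarpsearchError(Exception):
    """Base class for all package errors."""


class InputError(WarpsearchError, ValueError):
    """Invalid input data or parameters."""


class DimensionMismatchError(InputError):
    """Two series (or sample vectors) have different channel counts."""


class BasisMismatchError(InputError):
    """Two embeddings were produced against different basis sets."""


class InfeasibleSearchError(WarpsearchError, RuntimeError):
    """No feasible warping path / search region / evaluation budget."""
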