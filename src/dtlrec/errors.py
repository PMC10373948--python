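"""Exception hierarchy shared across the package."""


class DtlrecError(Exception):
    """Base class for all package errors."""


class NewickParseError(DtlrecError):
    """Malformed Newick input; message names the offending position when known."""


class TreeStructureError(DtlrecError):
    """Tree violates a structural precondition (rootedness, binarity, labels)."""


class InputError(DtlrecError):
    """Invalid or inconsistent user input (leaf maps, samples, pairing)."""


class NumericalError(DtlrecError):
    """A fixed-point iteration or optimisation failed to converge."""
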