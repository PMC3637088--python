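"""Exception hierarchy shared across the package."""


class TreeDerepError(Exception):
    """Base class for all errors raised by treederep."""


class NewickParseError(TreeDerepError):
    """Malformed Newick input.

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    offset:
        Zero-based character offset into the input at which the problem
        was detected.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class ValidationError(TreeDerepError):
    """Structurally valid input that violates a semantic constraint."""
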