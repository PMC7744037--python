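"""Exception hierarchy.

Everything user-facing raises one of these so the CLI can map data problems
to exit code 1 and usage problems to exit code 2.
"""


class MMPhyloError(Exception):
    """Base class for all package errors."""


class ValidationError(MMPhyloError, ValueError):
    """A model, tree or alignment violates an invariant.

    The message names the offending field.
    """


class ModelParseError(MMPhyloError, ValueError):
    """A model-notation string or config could not be parsed."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class DataParseError(MMPhyloError, ValueError):
    """A tree or alignment file could not be parsed."""
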