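"""Exception types shared across the package."""


class LitmineError(Exception):
    """Base class for all litmine errors."""


class FormatError(LitmineError):
    """Raised when an input file violates its documented format."""


class ParameterError(LitmineError, ValueError):
    """Raised when an operation is called with invalid parameters."""


class MeshLookupError(LitmineError, KeyError):
    """Raised when a MeSH descriptor UI or name is not in the vocabulary."""

    def __init__(self, ui: str):
        super().__init__(ui)
        self.ui = ui

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown MeSH descriptor: {self.ui!r}"
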