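"""Exception types: user/validation errors exit 2 from the CLI, internal errors 1."""


class LfqMinerError(Exception):
    """Base class for package errors."""


class FormatError(LfqMinerError):
    """Input file does not match the expected dialect."""


class ValidationError(LfqMinerError):
    """Inputs are readable but violate a contract (bad parameter, mismatch)."""


class NotFoundError(LfqMinerError):
    """A lookup query matched nothing."""

    def __init__(self, query: str):
        self.query = query
        super().__init__(f"no protein matches query {query!r}")
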