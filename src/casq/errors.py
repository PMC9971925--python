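"""Exception hierarchy shared across the package."""


class CasqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CasqError):
    """A parameter or configuration value is out of its allowed range."""


class ValidationError(CasqError):
    """An input value violates a precondition."""


class ParseError(CasqError):
    """An input document could not be parsed."""


class SchemaError(CasqError):
    """A tabular input is missing required columns."""


class LookupError_(CasqError):
    """A requested identifier is not present in a store."""

    def __init__(self, identifier: str, message: str | None = None):
        self.identifier = identifier
        super().__init__(message or f"unknown identifier: {identifier!r}")


class CycleError(CasqError):
    """A composite annotation contains a cycle among intermediate nodes."""

    def __init__(self, nodes):
        self.nodes = tuple(nodes)
        super().__init__(f"cycle among intermediate nodes: {', '.join(self.nodes)}")


class CorpusError(CasqError):
    """A corpus-level invariant (e.g. unique entity ids) is violated."""


class QueryError(CasqError):
    """A query cannot be embedded under the requested method."""
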