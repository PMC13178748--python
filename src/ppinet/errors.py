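"""Exception hierarchy shared across the pipeline stages."""


class PPINetError(Exception):
    """Base class for all package errors."""


class MalformedInputError(PPINetError):
    """A parsed stream violates its format contract.

    Carries the 1-based line number when one is known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DuplicateTermError(MalformedInputError):
    """A gene-set library defines the same term name twice."""


class SourceUnavailableError(PPINetError):
    """An interaction provider failed (network/IO), as opposed to
    returning a legitimately empty result."""


class DegenerateInputError(PPINetError):
    """The operation is undefined on this input (e.g. a single-node
    graph for degree centrality, an empty query after intersection)."""


class UndefinedMetricError(DegenerateInputError):
    """A graph statistic is undefined (e.g. modularity of an edgeless
    network)."""


class ConvergenceError(PPINetError):
    """An iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (residual {residual:.3e})"
        super().__init__(message)


class ConfigurationError(PPINetError):
    """A run configuration or synthetic-data specification violates its
    invariants."""
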