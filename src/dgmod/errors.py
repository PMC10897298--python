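"""Exception hierarchy.

Everything raised on purpose derives from :class:`DGModError` so callers
(and the CLI) can distinguish our failures from genuine bugs.
"""


class DGModError(Exception):
    """Base class for all package errors."""


class GraphFormatError(DGModError):
    """A graph file could not be parsed."""


class UnsupportedFormatError(GraphFormatError):
    """The file parsed but describes something we do not model (e.g. a
    directed graph)."""


class ValidationError(DGModError):
    """An argument violates a documented precondition."""


class FixtureNotFoundError(DGModError, KeyError):
    """Unknown bundled fixture name."""


class UndefinedMetricError(DGModError):
    """A quality metric was requested where its formula is undefined
    (empty graph, singleton community, isolated node, ...)."""


class ConfigError(DGModError):
    """Invalid search configuration."""


class GenerationError(DGModError):
    """Synthetic-graph generation failed after bounded retries."""
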