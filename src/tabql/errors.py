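"""Exception taxonomy.

Usage errors (bad configuration) are distinguished from runtime errors
(bad data, missing files) so the CLI can map them to distinct exit codes.
"""


class TabqlError(Exception):
    """Base class for all package errors."""


class ConfigError(TabqlError):
    """Invalid job configuration: unknown keys, bad filter parameters,
    patterns that do not compile, duplicate table names."""


class FilterError(TabqlError):
    """A line-filter step failed on a concrete input line."""

    def __init__(self, message: str, *, step: int | None = None,
                 line_number: int | None = None):
        ctx = []
        if step is not None:
            ctx.append(f"filter step {step}")
        if line_number is not None:
            ctx.append(f"input line {line_number}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.step = step
        self.line_number = line_number


class LoadError(TabqlError):
    """Loading a table into SQLite failed (empty input, name conflict,
    declared schema mismatch)."""


class QueryError(TabqlError):
    """Executing a SQL query failed or the statement was rejected."""


class ScenarioError(TabqlError):
    """A packaged scenario cannot be computed on the given input
    (e.g. no features below the mass threshold)."""
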