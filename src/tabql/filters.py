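"""Streaming line-filter pipeline.

A *line filter* consumes one TAB-separated line and emits zero or more
TAB-separated lines. Filters compose in declared order: the output stream
of step *k* is the input stream of step *k+1*, so running a pipeline is
the left-to-right fold of its steps over the document. The contract is
streaming — no filter needs to see the whole file.

Available filter kinds
----------------------
``exclude_comments``
    Drop lines whose first field starts with a comment character
    (default ``#``).
``regex_line``
    Include, exclude, or rewrite whole lines by a regular expression.
    Include/exclude use unanchored search semantics; replace substitutes
    every occurrence and honours backreferences (``\\1`` ... ``\\9``).
``select_columns``
    Keep columns by 1-based index, in the given order; indices may
    repeat. Indices past the end of a ragged line yield empty fields.
``add_column``
    Prepend or append a field: either a fixed text value or an
    incrementing index. The index counts lines seen by this step
    (i.e. after any upstream filters), starting at a configurable value.
``replace_column``
    Apply a regex substitution to a single column, leaving every other
    field byte-identical.
``normalize``
    Convert list-valued fields to first normal form. With one listed
    column whose field splits into *n* items, the line becomes *n*
    lines, one item each. With several listed columns the i-th output
    line carries the i-th item of every listed column (a parallel zip,
    not a cross product). Items are whitespace-trimmed; unequal list
    lengths are padded with empty strings (a warning is emitted).

Every filter spec round-trips losslessly through a plain JSON record
(``spec_to_dict`` / ``spec_from_dict``), which is also the form filters
take in the job configuration file.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

from .errors import ConfigError, FilterError
from .tabio import TabularLine, join_fields, split_line

__all__ = [
    "ExcludeComments",
    "RegexLine",
    "SelectColumns",
    "AddColumn",
    "ReplaceColumn",
    "Normalize",
    "LineFilterSpec",
    "spec_to_dict",
    "spec_from_dict",
    "compile_filter",
    "run_pipeline",
    "filter_text",
]


# ---------------------------------------------------------------------------
# Filter specifications (declarative, JSON-serializable)

@dataclass(frozen=True)
class ExcludeComments:
    comment_chars: tuple[str, ...] = ("#",)
    kind = "exclude_comments"

    def __post_init__(self):
        if not self.comment_chars:
            raise ConfigError("exclude_comments: comment_chars must be nonempty")
        for c in self.comment_chars:
            if len(c) != 1:
                raise ConfigError(
                    f"exclude_comments: comment characters must be single "
                    f"characters, got {c!r}")


@dataclass(frozen=True)
class RegexLine:
    pattern: str
    action: str  # include | exclude | replace
    replacement: str | None = None
    kind = "regex_line"

    def __post_init__(self):
        if self.action not in ("include", "exclude", "replace"):
            raise ConfigError(
                f"regex_line: action must be include, exclude or replace, "
                f"got {self.action!r}")
        if (self.replacement is not None) != (self.action == "replace"):
            raise ConfigError(
                "regex_line: replacement is required for action=replace "
                "and forbidden otherwise")
        _compile_pattern(self.pattern, "regex_line")


@dataclass(frozen=True)
class SelectColumns:
    columns: tuple[int, ...]
    kind = "select_columns"

    def __post_init__(self):
        if not self.columns:
            raise ConfigError("select_columns: column list must be nonempty")
        _check_indices(self.columns, "select_columns")


@dataclass(frozen=True)
class AddColumn:
    position: str = "append"  # prepend | append
    text: str | None = None
    start: int | None = None  # incrementing index starting value
    kind = "add_column"

    def __post_init__(self):
        if self.position not in ("prepend", "append"):
            raise ConfigError(
                f"add_column: position must be prepend or append, "
                f"got {self.position!r}")
        if (self.text is None) == (self.start is None):
            raise ConfigError(
                "add_column: exactly one of text (fixed value) or start "
                "(incrementing index) must be given")


@dataclass(frozen=True)
class ReplaceColumn:
    column: int
    pattern: str
    replacement: str
    kind = "replace_column"

    def __post_init__(self):
        _check_indices((self.column,), "replace_column")
        _compile_pattern(self.pattern, "replace_column")


@dataclass(frozen=True)
class Normalize:
    columns: tuple[int, ...]
    separator: str = ","
    kind = "normalize"

    def __post_init__(self):
        if not self.columns:
            raise ConfigError("normalize: column list must be nonempty")
        _check_indices(self.columns, "normalize")
        if not self.separator:
            raise ConfigError("normalize: separator must be nonempty")


LineFilterSpec = (ExcludeComments | RegexLine | SelectColumns | AddColumn
                  | ReplaceColumn | Normalize)

_SPEC_CLASSES: dict[str, type] = {
    cls.kind: cls
    for cls in (ExcludeComments, RegexLine, SelectColumns, AddColumn,
                ReplaceColumn, Normalize)
}

# JSON keys accepted per kind (beyond "filter")
_SPEC_FIELDS: dict[str, tuple[str, ...]] = {
    "exclude_comments": ("comment_chars",),
    "regex_line": ("pattern", "action", "replacement"),
    "select_columns": ("columns",),
    "add_column": ("position", "text", "start"),
    "replace_column": ("column", "pattern", "replacement"),
    "normalize": ("columns", "separator"),
}


def _compile_pattern(pattern: str, where: str) -> re.Pattern:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise ConfigError(f"{where}: invalid regex {pattern!r}: {exc}") from exc


def _check_indices(indices: Sequence[int], where: str) -> None:
    for i in indices:
        if not isinstance(i, int) or isinstance(i, bool) or i < 1:
            raise ConfigError(
                f"{where}: column indices are 1-based integers, got {i!r}")


def spec_to_dict(spec: LineFilterSpec) -> dict:
    """Render a filter spec as its JSON configuration record."""
    rec: dict = {"filter": spec.kind}
    for name in _SPEC_FIELDS[spec.kind]:
        value = getattr(spec, name)
        if value is None:
            continue
        rec[name] = list(value) if isinstance(value, tuple) else value
    return rec


def spec_from_dict(rec: dict) -> LineFilterSpec:
    """Parse a JSON filter record; unknown kinds or keys are rejected."""
    if not isinstance(rec, dict):
        raise ConfigError(f"filter record must be an object, got {rec!r}")
    try:
        kind = rec["filter"]
    except KeyError:
        raise ConfigError("filter record is missing the 'filter' key") from None
    cls = _SPEC_CLASSES.get(kind)
    if cls is None:
        raise ConfigError(
            f"unknown filter kind {kind!r}; expected one of "
            f"{sorted(_SPEC_CLASSES)}")
    allowed = _SPEC_FIELDS[kind]
    unknown = set(rec) - {"filter", *allowed}
    if unknown:
        raise ConfigError(
            f"{kind}: unknown keys {sorted(unknown)}; allowed: {list(allowed)}")
    kwargs = {}
    for name in allowed:
        if name in rec:
            value = rec[name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Compilation to executable steps

# A step maps one line's fields to zero or more output lines' fields.
FilterStep = Callable[[TabularLine], list[TabularLine]]


def compile_filter(spec: LineFilterSpec) -> FilterStep:
    """Build a fresh executable step for *spec*.

    Steps may be stateful (the incrementing-index column counts lines it
    has seen), so a new step must be compiled per pipeline run.
    """
    if isinstance(spec, ExcludeComments):
        chars = frozenset(spec.comment_chars)

        def step(fields: TabularLine) -> list[TabularLine]:
            first = fields[0][:1] if fields else ""
            return [] if first and first in chars else [fields]

        return step

    if isinstance(spec, RegexLine):
        rx = _compile_pattern(spec.pattern, "regex_line")
        if spec.action == "replace":
            repl = spec.replacement

            def step(fields: TabularLine) -> list[TabularLine]:
                return [split_line(rx.sub(repl, join_fields(fields)))]

        elif spec.action == "include":

            def step(fields: TabularLine) -> list[TabularLine]:
                return [fields] if rx.search(join_fields(fields)) else []

        else:  # exclude

            def step(fields: TabularLine) -> list[TabularLine]:
                return [] if rx.search(join_fields(fields)) else [fields]

        return step

    if isinstance(spec, SelectColumns):
        idx = [i - 1 for i in spec.columns]

        def step(fields: TabularLine) -> list[TabularLine]:
            n = len(fields)
            # ragged lines: missing fields read as empty strings
            return [[fields[i] if i < n else "" for i in idx]]

        return step

    if isinstance(spec, AddColumn):
        if spec.text is not None:
            value = spec.text
            if spec.position == "prepend":
                def step(fields):
                    return [[value, *fields]]
            else:
                def step(fields):
                    return [[*fields, value]]
            return step

        counter = iter(range(spec.start, 2**63))
        if spec.position == "prepend":
            def step(fields):
                return [[str(next(counter)), *fields]]
        else:
            def step(fields):
                return [[*fields, str(next(counter))]]
        return step

    if isinstance(spec, ReplaceColumn):
        rx = _compile_pattern(spec.pattern, "replace_column")
        col = spec.column - 1
        repl = spec.replacement

        def step(fields: TabularLine) -> list[TabularLine]:
            out = list(fields)
            if col >= len(out):  # ragged line: substitute on an empty field
                out.extend([""] * (col + 1 - len(out)))
            out[col] = rx.sub(repl, out[col])
            return [out]

        return step

    if isinstance(spec, Normalize):
        cols = [i - 1 for i in spec.columns]
        sep = spec.separator

        def step(fields: TabularLine) -> list[TabularLine]:
            n_fields = len(fields)
            items: dict[int, list[str]] = {}
            for c in cols:
                raw = fields[c] if c < n_fields else ""
                items[c] = [part.strip() for part in raw.split(sep)]
            width = max(len(v) for v in items.values())
            if len({len(v) for v in items.values()}) > 1:
                warnings.warn(
                    f"normalize: unequal list lengths across columns "
                    f"{[c + 1 for c in cols]} on line {join_fields(fields)!r}; "
                    f"padding with empty strings",
                    stacklevel=2)
            out = []
            for i in range(width):
                row = list(fields)
                if len(row) < max(cols) + 1:
                    row.extend([""] * (max(cols) + 1 - len(row)))
                for c in cols:
                    lst = items[c]
                    row[c] = lst[i] if i < len(lst) else ""
                out.append(row)
            return out

        return step

    raise ConfigError(f"unknown filter spec {spec!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Pipeline execution

def run_pipeline(lines: Iterable[TabularLine],
                 pipeline: Sequence[LineFilterSpec]) -> Iterator[TabularLine]:
    """Stream *lines* through *pipeline*, yielding surviving/derived lines.

    Relative order is preserved: every output attributable to input line
    *i* precedes those of line *j* whenever *i* < *j*. Errors raised by a
    step are annotated with the step index and the 1-based input line
    number being processed.
    """
    steps = [compile_filter(spec) for spec in pipeline]
    state = {"line": 0}

    def source() -> Iterator[TabularLine]:
        for fields in lines:
            state["line"] += 1
            yield fields

    def feed(upstream: Iterator[TabularLine], step: FilterStep,
             index: int) -> Iterator[TabularLine]:
        for fields in upstream:
            try:
                produced = step(fields)
            except FilterError:
                raise
            except Exception as exc:
                raise FilterError(str(exc), step=index,
                                  line_number=state["line"]) from exc
            yield from produced

    stream: Iterator[TabularLine] = source()
    for k, step in enumerate(steps, start=1):
        stream = feed(stream, step, k)
    return stream


def filter_text(text: str, pipeline: Sequence[LineFilterSpec]) -> str:
    """Convenience: run a pipeline over a document given as TSV text."""
    from .tabio import format_document, parse_document
    return format_document(run_pipeline(parse_document(text), pipeline))
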