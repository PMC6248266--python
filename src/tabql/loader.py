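"""Load filtered tabular data into typed SQLite tables.

Loading is two-pass: the filtered lines are fully inspected first (field
counts and per-column SQLite affinity — Integer, Real or Text), the
schema is fixed, and only then are rows inserted. This guarantees that
the declared type of a column can never be narrowed by a later row.

Conventions
-----------
* Default table names are ``t1, t2, ...`` by position among the job's
  inputs; default column names are ``c1, c2, ...`` in field order.
* When the first row is flagged as a header it supplies column names
  (sanitized into SQL identifiers) and is excluded from inference and
  loading.
* Empty fields are stored as NULL; short (ragged) rows are padded with
  NULL to the widest row observed.
* Loading into an existing table name fails unless ``replace`` is set,
  in which case the table is dropped and recreated.
"""
from __future__ import annotations

import re
import sqlite3
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigError, LoadError
from .filters import LineFilterSpec, run_pipeline
from .tabio import TabularLine, read_document

__all__ = [
    "ColumnSchema",
    "TableSpec",
    "TableSchema",
    "infer_column_type",
    "sanitize_identifier",
    "load_table",
    "load_job",
]

_INTEGER_RE = re.compile(r"[+-]?\d+")
_REAL_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


@dataclass(frozen=True)
class ColumnSchema:
    name: str
    sqltype: str  # "INTEGER" | "REAL" | "TEXT"


@dataclass(frozen=True)
class TableSchema:
    table_name: str
    columns: tuple[ColumnSchema, ...]
    row_count: int


@dataclass
class TableSpec:
    """One tabular input destined for one database table.

    ``source`` is a file path (or an already-materialized iterable of
    TAB-split lines). ``column_names`` takes precedence over header
    names when both are given; the header row is still consumed.
    ``load_columns`` selects a subset of columns by header name.
    """
    source: str | Path | Iterable[TabularLine]
    filters: Sequence[LineFilterSpec] = ()
    table_name: str | None = None
    column_names: Sequence[str] | None = None
    first_row_is_header: bool = False
    load_columns: Sequence[str] | None = None
    indexes: Sequence[Sequence[str]] = ()
    replace: bool = False


def infer_column_type(values: Iterable[str]) -> str:
    """Infer the SQLite affinity of a column from its text values.

    INTEGER if every non-empty value is an optionally-signed decimal
    integer; else REAL if every non-empty value is a decimal or
    scientific-notation number; else TEXT. A column with no non-empty
    values is TEXT. Surrounding whitespace is tolerated; "NaN"/"Inf"
    spellings are TEXT (conservative typing keeps arithmetic clean).
    """
    seen_any = False
    is_int = True
    is_real = True
    for v in values:
        s = v.strip()
        if not s:
            continue
        seen_any = True
        if is_int and not _INTEGER_RE.fullmatch(s):
            is_int = False
        if not is_int and not _REAL_RE.fullmatch(s):
            is_real = False
            break
    if not seen_any:
        return "TEXT"
    if is_int:
        return "INTEGER"
    if is_real:
        return "REAL"
    return "TEXT"


def sanitize_identifier(raw: str, position: int) -> str:
    """Coerce arbitrary text into a safe unquoted SQL identifier.

    Non-alphanumeric characters become underscores; a leading digit is
    guarded with an underscore; empty (or all-invalid collapsing to
    empty) input falls back to the default name ``c<position>``.
    Collision handling is the caller's job (see _unique_names).
    """
    name = re.sub(r"\W", "_", raw.strip())
    if not name or set(name) == {"_"}:
        return f"c{position}"
    if name[0].isdigit():
        name = "_" + name
    return name


def _unique_names(raw_names: Sequence[str]) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for pos, raw in enumerate(raw_names, start=1):
        name = sanitize_identifier(raw, pos)
        if name in seen:
            k = 2
            while f"{name}_{k}" in seen:
                k += 1
            name = f"{name}_{k}"
        seen.add(name)
        out.append(name)
    return out


def _materialize(spec: TableSpec) -> list[TabularLine]:
    if isinstance(spec.source, (str, Path)):
        try:
            lines: Iterable[TabularLine] = read_document(spec.source)
            return list(run_pipeline(lines, spec.filters))
        except OSError as exc:
            raise LoadError(f"cannot read input {spec.source}: {exc}") from exc
    return list(run_pipeline(spec.source, spec.filters))


def _cell(value: str, sqltype: str):
    s = value.strip() if sqltype != "TEXT" else value
    if s == "":
        return None
    if sqltype == "INTEGER":
        return int(s)
    if sqltype == "REAL":
        return float(s)
    return value


def load_table(db: str | Path, spec: TableSpec, *,
               position: int = 1) -> TableSchema:
    """Filter one input, infer its schema, and load it as one table.

    *position* is the table's 1-based ordinal among the job's inputs,
    used for the default ``t<k>`` name. Returns the realized schema
    including the loaded row count.
    """
    rows = _materialize(spec)

    header: TabularLine | None = None
    if spec.first_row_is_header:
        if rows:
            header = rows[0]
            rows = rows[1:]

    width = max((len(r) for r in rows), default=0)

    # Column names: explicit list > header row > defaults c1, c2, ...
    if spec.column_names is not None:
        raw_names = list(spec.column_names)
        if rows and len(raw_names) != width:
            raise LoadError(
                f"table {spec.table_name or f't{position}'}: declared "
                f"{len(raw_names)} column names but data has {width} fields")
        width = len(raw_names)
    elif header is not None:
        width = max(width, len(header))
        raw_names = list(header) + [""] * (width - len(header))
    else:
        raw_names = [f"c{i}" for i in range(1, width + 1)]
    names = _unique_names(raw_names)

    # Optional subset selection by header name (pre-sanitization names).
    if spec.load_columns is not None:
        if header is None and spec.column_names is None:
            raise ConfigError(
                "load_columns requires a header row or explicit column_names")
        lookup = {raw.strip(): i for i, raw in enumerate(raw_names)}
        lookup.update({n: i for i, n in enumerate(names)})
        try:
            keep = [lookup[c] for c in spec.load_columns]
        except KeyError as exc:
            raise ConfigError(
                f"load_columns: no column named {exc.args[0]!r}; "
                f"available: {names}") from None
        names = [names[i] for i in keep]
        rows = [[r[i] if i < len(r) else "" for i in keep] for r in rows]
        width = len(keep)

    table_name = spec.table_name or f"t{position}"
    if not re.fullmatch(r"\w+", table_name):
        raise ConfigError(f"invalid table name {table_name!r}")

    if width == 0:
        raise LoadError(
            f"table {table_name}: no rows and no declared columns after "
            f"filtering; nothing to infer")

    sqltypes = [
        infer_column_type(r[i] if i < len(r) else "" for r in rows)
        for i in range(width)
    ]
    columns = tuple(ColumnSchema(n, t) for n, t in zip(names, sqltypes))

    ragged = any(len(r) != width for r in rows)
    if ragged:
        warnings.warn(
            f"table {table_name}: ragged rows padded with NULL to "
            f"{width} fields", stacklevel=2)

    con = sqlite3.connect(db)
    try:
        exists = con.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?",
            (table_name,)).fetchone()
        if exists:
            if not spec.replace:
                raise LoadError(
                    f"table {table_name} already exists in {db}; set "
                    f"replace to drop and recreate it")
            con.execute(f'DROP TABLE "{table_name}"')
        decl = ", ".join(f'"{c.name}" {c.sqltype}' for c in columns)
        con.execute(f'CREATE TABLE "{table_name}" ({decl})')
        placeholders = ", ".join("?" * width)
        con.executemany(
            f'INSERT INTO "{table_name}" VALUES ({placeholders})',
            ([_cell(r[i], sqltypes[i]) if i < len(r) else None
              for i in range(width)] for r in rows))
        for k, index_cols in enumerate(spec.indexes, start=1):
            missing = [c for c in index_cols if c not in names]
            if missing:
                raise ConfigError(
                    f"index on {table_name}: unknown columns {missing}")
            cols_sql = ", ".join(f'"{c}"' for c in index_cols)
            con.execute(
                f'CREATE INDEX "idx_{table_name}_{k}" '
                f'ON "{table_name}" ({cols_sql})')
        con.commit()
    finally:
        con.close()

    return TableSchema(table_name, columns, len(rows))


def load_job(db: str | Path, specs: Sequence[TableSpec]) -> list[TableSchema]:
    """Load any number of inputs into a new or existing database.

    Default table names ``t1, t2, ...`` are assigned by position among
    the inputs; names must be pairwise distinct after defaulting.
    """
    names = [s.table_name or f"t{k}" for k, s in enumerate(specs, start=1)]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigError(f"duplicate table names: {sorted(dupes)}")
    if not specs:
        # vacuous job: still leave a valid (empty) database file behind
        sqlite3.connect(db).close()
        return []
    return [
        load_table(db, spec, position=k)
        for k, spec in enumerate(specs, start=1)
    ]
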