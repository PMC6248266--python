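"""Execute regex-extended SQL against a loaded database.

Three scalar functions are registered on every connection so queries can
use regular expressions directly:

``re_search(pattern, subject)``
    1 if *pattern* occurs anywhere in *subject*, else 0.
``re_match(pattern, subject)``
    1 if *pattern* matches at the start of *subject*, else 0.
``re_replace(pattern, replacement, subject)``
    *subject* with every occurrence of *pattern* substituted;
    backreferences are honoured.

Any NULL argument yields NULL, matching SQL's treatment of missing
values. Query mode is strictly read-only: the database is opened with
``mode=ro`` and only a single SELECT (or WITH ... SELECT) statement is
accepted, so the saved database artifact can never be mutated by a
query.
"""
from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import QueryError

__all__ = [
    "QueryJob",
    "ResultTable",
    "register_regex_functions",
    "execute_query",
    "write_tabular",
    "query_existing_db",
]


@dataclass(frozen=True)
class QueryJob:
    db: str | Path
    sql: str
    include_header: bool = True
    null_render: str = ""
    params: Mapping[str, Any] | None = None


@dataclass(frozen=True)
class ResultTable:
    column_names: tuple[str, ...]
    rows: tuple[tuple, ...]


# sqlite reduces exceptions raised inside user functions to a generic
# message; remember the detail per connection so execute_query can
# re-surface it naming the offending function.
_REGEX_ERRORS: dict[int, list[str]] = {}


def register_regex_functions(con: sqlite3.Connection) -> None:
    """Install re_search / re_match / re_replace on *con*."""
    last_error = _REGEX_ERRORS.setdefault(id(con), [])

    def guard(name, fn):
        def wrapped(*args):
            if any(a is None for a in args):
                return None
            try:
                return fn(*args)
            except re.error as exc:
                last_error.append(f"{name}: invalid pattern: {exc}")
                raise
        return wrapped

    con.create_function(
        "re_search", 2,
        guard("re_search", lambda p, s: 1 if re.search(p, str(s)) else 0),
        deterministic=True)
    con.create_function(
        "re_match", 2,
        guard("re_match", lambda p, s: 1 if re.match(p, str(s)) else 0),
        deterministic=True)
    con.create_function(
        "re_replace", 3,
        guard("re_replace", lambda p, r, s: re.sub(p, r, str(s))),
        deterministic=True)


_COMMENT_RE = re.compile(r"--[^\n]*|/\*.*?\*/", re.S)


def _first_keyword(sql: str) -> str:
    stripped = _COMMENT_RE.sub(" ", sql).strip()
    token = re.match(r"[A-Za-z]*", stripped)
    return token.group(0).upper() if token else ""


def _connect_readonly(db: str | Path) -> sqlite3.Connection:
    path = Path(db)
    if not path.is_file():
        raise QueryError(f"database file not found: {db}")
    uri = f"file:{path.as_posix()}?mode=ro"
    return sqlite3.connect(uri, uri=True)


def execute_query(job: QueryJob) -> ResultTable:
    """Run one read-only statement and collect its typed result rows.

    Rows come back in the engine's result order; queries that need a
    stable output order must say so with ORDER BY — no ordering is ever
    injected.
    """
    keyword = _first_keyword(job.sql)
    if keyword not in ("SELECT", "WITH"):
        raise QueryError(
            f"only read-only SELECT statements are allowed in query mode; "
            f"got a {keyword or 'empty'} statement")
    con = _connect_readonly(job.db)
    try:
        register_regex_functions(con)
        try:
            cur = con.execute(job.sql, dict(job.params or {}))
        except sqlite3.Warning as exc:
            raise QueryError(f"rejected multi-statement query: {exc}") from exc
        except (sqlite3.OperationalError, sqlite3.DatabaseError,
                sqlite3.ProgrammingError) as exc:
            detail = _REGEX_ERRORS.get(id(con), [])
            extra = f" [{detail[-1]}]" if detail else ""
            raise QueryError(
                f"SQL error: {exc}{extra}\nquery was:\n{job.sql}") from exc
        names = tuple(d[0] for d in cur.description) if cur.description else ()
        try:
            rows = tuple(tuple(r) for r in cur.fetchall())
        except (sqlite3.OperationalError, sqlite3.DatabaseError) as exc:
            detail = _REGEX_ERRORS.get(id(con), [])
            extra = f" [{detail[-1]}]" if detail else ""
            raise QueryError(
                f"SQL error: {exc}{extra}\nquery was:\n{job.sql}") from exc
    finally:
        _REGEX_ERRORS.pop(id(con), None)
        con.close()
    return ResultTable(names, rows)


def _render(value, null_render: str) -> str:
    if value is None:
        return null_render
    if isinstance(value, float):
        return repr(value)  # shortest round-trip decimal form
    return str(value)


def write_tabular(result: ResultTable, include_header: bool = True,
                  null_render: str = "") -> str:
    """Serialize a result as TSV text (newline-terminated lines).

    Integers print without a decimal point; reals print in shortest
    round-trip form; NULL prints as *null_render* (default empty cell).
    """
    out = []
    if include_header:
        out.append("\t".join(result.column_names))
    for row in result.rows:
        out.append("\t".join(_render(v, null_render) for v in row))
    return "".join(line + "\n" for line in out)


def query_existing_db(db: str | Path, sql: str, *,
                      include_header: bool = True, null_render: str = "",
                      params: Mapping[str, Any] | None = None) -> str:
    """Query an existing database file and return TSV text.

    Pure composition of :func:`execute_query` and :func:`write_tabular`;
    never creates or modifies a database, so several queries can be run
    against the same saved artifact.
    """
    job = QueryJob(db=db, sql=sql, include_header=include_header,
                   null_render=null_render, params=params)
    return write_tabular(execute_query(job), include_header, null_render)
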