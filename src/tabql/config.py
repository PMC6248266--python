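"""Declarative job configuration shared by all three CLI entry points.

A job is described by one JSON document: any number of tabular inputs
(each with its own filter pipeline, table name, column options and
optional index declarations), an optional SQL query, and optional
database options. The query may be omitted when the SQLite database is
the only desired output.

Validation is strict — unknown keys are rejected, and errors carry a
JSON-pointer to the offending key. The published JSON schema shipped at
``tabql/schema/job-config.schema.json`` is generated from these models.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import ConfigError
from .filters import LineFilterSpec, spec_from_dict, spec_to_dict

__all__ = ["TableConfig", "QueryConfig", "DbConfig", "JobConfig",
           "load_job_config", "published_schema"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TableConfig(_Strict):
    """One tabular input file and how to load it."""
    file: str
    table: Optional[str] = None
    column_names: Optional[list[str]] = None
    first_row_is_header: bool = False
    load_columns: Optional[list[str]] = None
    filters: list[dict] = []
    indexes: list[list[str]] = []
    replace: bool = False

    @field_validator("filters")
    @classmethod
    def _filters_parse(cls, v: list[dict]) -> list[dict]:
        for i, rec in enumerate(v):
            try:
                spec_from_dict(rec)
            except ConfigError as exc:
                raise ValueError(f"filters[{i}]: {exc}") from exc
        return v

    def filter_specs(self) -> list[LineFilterSpec]:
        return [spec_from_dict(rec) for rec in self.filters]


class QueryConfig(_Strict):
    sql: Optional[str] = None
    sql_file: Optional[str] = None
    include_header: bool = True
    null_render: str = ""

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "QueryConfig":
        if (self.sql is None) == (self.sql_file is None):
            raise ValueError("exactly one of 'sql' or 'sql_file' is required")
        return self

    def sql_text(self, base_dir: Path | None = None) -> str:
        if self.sql is not None:
            return self.sql
        path = Path(self.sql_file)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return path.read_text(encoding="utf-8")


class DbConfig(_Strict):
    path: Optional[str] = None
    save: bool = False
    existing: bool = False

    @model_validator(mode="after")
    def _path_when_needed(self) -> "DbConfig":
        if (self.save or self.existing) and self.path is None:
            raise ValueError("'path' is required when save or existing is set")
        return self


class JobConfig(_Strict):
    tables: list[TableConfig] = []
    query: Optional[QueryConfig] = None
    db: Optional[DbConfig] = None


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(p) for p in loc) if loc else "/"


def load_job_config(source: str | Path | dict) -> JobConfig:
    """Parse and validate a job configuration.

    *source* may be a path to a JSON file or an already-parsed mapping.
    Raises :class:`ConfigError` with a JSON-pointer to the first
    offending key on any schema violation.
    """
    if isinstance(source, (str, Path)):
        try:
            data = json.loads(Path(source).read_text(encoding="utf-8"))
        except OSError as exc:
            raise ConfigError(f"cannot read config {source}: {exc}") from exc
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config {source} is not valid JSON: {exc}") from exc
    else:
        data = source
    try:
        return JobConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        raise ConfigError(
            f"invalid job config at {_pointer(tuple(first['loc']))}: "
            f"{first['msg']}") from exc


def published_schema() -> dict:
    """The JSON schema these models publish (also shipped as a file)."""
    return JobConfig.model_json_schema()
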