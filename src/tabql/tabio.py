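"""Reading and writing TAB-separated text.

The dialect is deliberately raw: a line is its fields joined by single TAB
characters, with no quoting or escaping, matching the conventions of
bioinformatics tabular formats (BLAST outfmt 6, PSM reports, feature
tables). Both "\\n" and "\\r\\n" line endings are accepted on input;
output always uses "\\n".
"""
from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

TAB = "\t"

TabularLine = list[str]  # the TAB-split cells of one line


def split_line(line: str) -> TabularLine:
    return line.split(TAB)


def join_fields(fields: Iterable[str]) -> str:
    return TAB.join(fields)


def iter_lines(text: str) -> Iterator[str]:
    """Yield raw lines of *text* without line terminators.

    A trailing newline does not produce a final empty line; an empty
    string is an empty document.
    """
    if not text:
        return
    if text.endswith("\n"):
        text = text[:-1]
    for raw in text.split("\n"):
        yield raw[:-1] if raw.endswith("\r") else raw


def parse_document(text: str) -> list[TabularLine]:
    return [split_line(raw) for raw in iter_lines(text)]


def format_document(lines: Iterable[Iterable[str]]) -> str:
    """Serialize rows of fields; every line, including the last, is
    newline-terminated. An empty document is the empty string."""
    out = io.StringIO()
    for fields in lines:
        out.write(join_fields(fields))
        out.write("\n")
    return out.getvalue()


def read_document(path: str | Path) -> Iterator[TabularLine]:
    """Stream the TAB-split lines of a file (universal newlines)."""
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for raw in fh:
            yield split_line(raw.rstrip("\n"))


def write_document(path: str | Path, lines: Iterable[Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for fields in lines:
            fh.write(join_fields(fields))
            fh.write("\n")
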