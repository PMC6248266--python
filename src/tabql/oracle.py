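"""Independent brute-force reference for the line-filter pipeline.

This module re-implements the filter semantics from scratch for
equivalence testing: whole-document, in-memory, string-based, and
sharing no code with :mod:`tabql.filters` (pipelines are given as plain
JSON filter records, not spec objects). It is deliberately naive — each
filter pass materializes the full intermediate document.
"""
from __future__ import annotations

import re

__all__ = ["reference_filter_oracle"]


def _apply_one(lines: list[str], rec: dict) -> list[str]:
    kind = rec["filter"]

    if kind == "exclude_comments":
        chars = tuple(rec.get("comment_chars", ["#"]))
        out = []
        for line in lines:
            first_field = line.split("\t", 1)[0]
            if first_field != "" and first_field[0] in chars:
                continue
            out.append(line)
        return out

    if kind == "regex_line":
        pattern, action = rec["pattern"], rec["action"]
        if action == "include":
            return [ln for ln in lines if re.search(pattern, ln)]
        if action == "exclude":
            return [ln for ln in lines if not re.search(pattern, ln)]
        return [re.sub(pattern, rec["replacement"], ln) for ln in lines]

    if kind == "select_columns":
        out = []
        for line in lines:
            cells = line.split("\t")
            picked = []
            for i in rec["columns"]:
                picked.append(cells[i - 1] if i - 1 < len(cells) else "")
            out.append("\t".join(picked))
        return out

    if kind == "add_column":
        out = []
        for ordinal, line in enumerate(lines):
            if rec.get("text") is not None:
                extra = rec["text"]
            else:
                extra = str(rec["start"] + ordinal)
            if rec.get("position", "append") == "prepend":
                out.append(extra + "\t" + line)
            else:
                out.append(line + "\t" + extra)
        return out

    if kind == "replace_column":
        col = rec["column"]
        out = []
        for line in lines:
            cells = line.split("\t")
            while len(cells) < col:
                cells.append("")
            cells[col - 1] = re.sub(rec["pattern"], rec["replacement"],
                                    cells[col - 1])
            out.append("\t".join(cells))
        return out

    if kind == "normalize":
        cols = rec["columns"]
        sep = rec.get("separator", ",")
        out = []
        for line in lines:
            cells = line.split("\t")
            while len(cells) < max(cols):
                cells.append("")
            lists = {c: [x.strip() for x in cells[c - 1].split(sep)]
                     for c in cols}
            n = max(len(v) for v in lists.values())
            for i in range(n):
                row = list(cells)
                for c in cols:
                    row[c - 1] = lists[c][i] if i < len(lists[c]) else ""
                out.append("\t".join(row))
        return out

    raise ValueError(f"oracle: unknown filter kind {kind!r}")


def reference_filter_oracle(lines: list[str],
                            pipeline: list[dict]) -> list[str]:
    """Fold raw TSV lines through *pipeline* (JSON filter records)."""
    current = list(lines)
    for rec in pipeline:
        current = _apply_one(current, rec)
    return current
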