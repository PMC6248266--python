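import sqlite3

import pytest

from tabql.loader import TableSpec, load_table


@pytest.fixture
def db_path(tmp_path):
    return tmp_path / "job.sqlite"


@pytest.fixture
def loaded_db(db_path):
    """A small database with one default-named, default-typed table."""
    load_table(db_path, TableSpec(
        source=[["a", "1"], ["b", "2"], ["c", "3"], ["d", "4"], ["e", "5"]]))
    return db_path


def read_rows(db, sql):
    con = sqlite3.connect(db)
    try:
        return con.execute(sql).fetchall()
    finally:
        con.close()
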