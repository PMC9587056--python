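"""Shared table conventions and error types.

Expression tables are pandas DataFrames indexed by ``fragment_id`` whose
first columns are the annotation metadata (``gene_id``, ``group_tag``)
followed by one column per sample.  Helpers here split/join those parts so
numeric code never has to special-case the metadata columns.
"""

from __future__ import annotations

import pandas as pd

META_COLS = ("gene_id", "group_tag")


class FragdexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FragdexError):
    """An invalid parameter value, named in the message."""


class DataError(FragdexError):
    """Malformed or inconsistent input data."""


def split_meta(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an annotated expression table into (metadata, sample values)."""
    meta_cols = [c for c in META_COLS if c in frame.columns]
    value_cols = [c for c in frame.columns if c not in META_COLS]
    return frame[meta_cols], frame[value_cols]


def join_meta(meta: pd.DataFrame, values: pd.DataFrame) -> pd.DataFrame:
    """Re-attach metadata columns in front of sample columns."""
    return pd.concat([meta.loc[values.index], values], axis=1)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(frame: pd.DataFrame, path, index_label=None) -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)
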