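"""TSV matrix input/output with channel-order validation.

All matrices are exchanged as tab-separated text: a header row of
column names and a first column of row identifiers. Channel-indexed
matrices (counts, opportunity, signatures) must carry the 96 canonical
channel names; files with the columns in a different order are accepted
and silently reordered to canonical (with a log note), anything else is
rejected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .channels import channel_names

log = logging.getLogger(__name__)

__all__ = ["write_matrix", "read_matrix"]


def write_matrix(path, values, row_ids, *, columns=None, row_label="sample") -> None:
    """Write a labelled matrix as TSV (17 significant digits)."""
    values = np.asarray(values)
    if columns is None:
        columns = channel_names()
    df = pd.DataFrame(values, index=pd.Index(row_ids, name=row_label), columns=columns)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path, *, expect_channels: bool = True) -> tuple[np.ndarray, list, list]:
    """Read a labelled TSV matrix; returns (values, row ids, column names).

    With ``expect_channels`` the columns must be exactly the 96 canonical
    channel names (any order); the returned values are in canonical
    column order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if expect_channels:
        canonical = channel_names()
        got = list(df.columns)
        if sorted(got) != sorted(canonical):
            raise ValueError(
                f"{path}: expected the 96 canonical channel columns, "
                f"got {len(got)} columns"
            )
        if got != canonical:
            log.info("%s: channel columns reordered to canonical order", path)
            df = df[canonical]
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)
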