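"""Readers/writers for the plain-text table formats the pipeline consumes.

Metadata tables are TSV with one header row and ``participant_id`` as the
first column. Abundance tables use the merged-profile layout common to
shotgun taxonomic profilers: first column is the feature name, remaining
columns are sample IDs, values are relative abundances. Internally the
package works with samples x features :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError


def read_metadata(path) -> pd.DataFrame:
    """Read a participant metadata TSV (participant_id first column)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "participant_id":
        raise SchemaError(
            f"metadata table must have 'participant_id' as first column, got {df.columns[0]!r}"
        )
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    """Write a participant metadata TSV, participant_id first."""
    if "participant_id" not in df.columns:
        raise SchemaError("metadata table lacks a 'participant_id' column")
    cols = ["participant_id"] + [c for c in df.columns if c != "participant_id"]
    df[cols].to_csv(path, sep="\t", index=False)


def read_abundance(path) -> pd.DataFrame:
    """Read a merged abundance table (features x samples on disk).

    Returns samples x features with sample IDs as index.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise SchemaError(f"abundance table {path} is empty")
    return df.T


def write_abundance(matrix: pd.DataFrame, path) -> None:
    """Write samples x features abundances in merged-profile layout."""
    out = matrix.T
    out.index.name = out.index.name or "feature"
    out.to_csv(path, sep="\t")
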