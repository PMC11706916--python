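"""Loaders for user-supplied published data files.

The ethnographic reference table and the worked-example site datasets
are distributed as journal supplements and cannot be redistributed
with this package.  Users who have downloaded them (and converted the
spreadsheets to CSV) can drop them into a directory — by default
``data/supplements/`` under the working tree — with these names:

``esm1_reference.csv``
    Ethnographic attribute scores: samples as rows, the six attribute
    columns, plus a ``Group`` column with labels 1-4.
``esm3_stafford.csv`` / ``esm6_tellbrak.csv``
    Taxon x sample count tables: taxa as rows, a ``Codes`` column with
    attribute codes (blank = unclassifiable), an optional ``Cat1``
    item-category column, and sample columns after the metadata.

Everything downstream (filtering, transform, both classification
methods) then works on the real data exactly as on the synthetic
fixtures.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from cropsift.classify import ReferenceSet
from cropsift.io import CountTable, read_counts

DEFAULT_DIR = Path("data/supplements")

FILENAMES = {
    "reference": "esm1_reference.csv",
    "stafford": "esm3_stafford.csv",
    "tellbrak": "esm6_tellbrak.csv",
}


def find_supplements(directory: str | Path = DEFAULT_DIR) -> dict[str, Path | None]:
    """Map supplement keys to existing paths (None where missing)."""
    directory = Path(directory)
    return {
        key: (directory / name if (directory / name).exists() else None)
        for key, name in FILENAMES.items()
    }


def load_reference(path: str | Path, group_column: str = "Group") -> ReferenceSet:
    """Load the ethnographic reference attribute table."""
    return ReferenceSet.from_csv(path, group_column=group_column)


def load_count_table(path: str | Path) -> CountTable:
    """Load a supplement-style count CSV, auto-detecting the layout.

    The attribute-code column is found case-insensitively (``Codes``),
    likewise the optional category column (``Cat1``); the first sample
    column is the first column after the metadata block.
    """
    header = pd.read_csv(path, nrows=0)
    columns = list(header.columns)[1:]  # first column is the taxon id

    def find(name: str) -> str | None:
        return next((c for c in columns if c.strip().lower() == name), None)

    code_column = find("codes") or find("code")
    if code_column is None:
        raise ValueError(f"no attribute-code column found in {path}")
    category_column = find("cat1") or find("category")
    meta = {code_column, category_column} - {None}
    last_meta = max(columns.index(c) for c in meta)
    try:
        first_sample_column = columns[last_meta + 1]
    except IndexError:
        raise ValueError(f"no sample columns found in {path}") from None
    return read_counts(
        path, code_column, first_sample_column, category_column
    )
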