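"""Reading, writing and screening of count tables.

Count tables arrive as CSV with taxa as rows and samples as columns
(the layout of published archaeobotanical supplements); a transposed
layout is accepted via a flag.  This module also applies the two
sample-eligibility screens used throughout the workflow — a minimum
item count and crop-dominance labelling — and persists classification
results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six valid weed-seed attribute codes, in canonical column order:
#: Big/Small x Headed/Free x Heavy/Light, restricted to the six
#: combinations that occur (big seeds are never light).
ATTRIBUTE_CODES: tuple[str, ...] = ("BHH", "BFH", "SHH", "SHL", "SFH", "SFL")

#: Sentinel for weed taxa whose attribute code is blank or unparseable.
UNCLASSIFIED = "UNCLASSIFIED"

#: Recognised item categories for taxa in a count table.
ITEM_CATEGORIES = ("grain", "rachis", "weed", "other")

_TRIPLOT_COLUMNS = ("grain", "rachis", "weeds")


class ConfigurationError(ValueError):
    """A named column, basis or option was missing or unrecognised."""


class DataError(ValueError):
    """The data region of an input file failed validation."""


def _normalise_code(raw: object) -> str:
    """Map a raw code cell to a canonical attribute code or UNCLASSIFIED."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNCLASSIFIED
    text = str(raw).strip().upper()
    if text in ATTRIBUTE_CODES:
        return text
    if text not in ("", "NAN", "NA"):
        logger.warning("unrecognised attribute code %r -> UNCLASSIFIED", raw)
    return UNCLASSIFIED


@dataclass
class CountTable:
    """Samples x taxa integer counts with per-taxon metadata.

    Parameters
    ----------
    counts
        DataFrame with taxa as the index and samples as columns;
        entries are non-negative integers.
    item_category
        Per-taxon category, one of ``grain``, ``rachis``, ``weed``,
        ``other``.
    attribute_code
        Per-taxon attribute code.  Weed taxa carry one of the six
        codes or :data:`UNCLASSIFIED`; non-weed taxa carry NA.
    """

    counts: pd.DataFrame
    item_category: pd.Series
    attribute_code: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if not counts.index.is_unique:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon ids: {dupes}")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            t, s = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative count at taxon {counts.index[t]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        if values.size and not np.allclose(values, np.round(values)):
            t, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise DataError(
                f"non-integer count at taxon {counts.index[t]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        self.counts = counts.astype(int)
        self.item_category = self.item_category.reindex(counts.index)
        self.attribute_code = self.attribute_code.reindex(counts.index)
        bad = set(self.item_category.dropna()) - set(ITEM_CATEGORIES)
        if bad:
            raise DataError(f"unknown item categories: {sorted(bad)}")
        is_weed = self.item_category == "weed"
        if self.attribute_code[is_weed].isna().any():
            missing = self.counts.index[is_weed & self.attribute_code.isna()]
            raise DataError(f"weed taxa without attribute code: {list(missing)}")
        if self.attribute_code[~is_weed].notna().any():
            extra = self.counts.index[~is_weed & self.attribute_code.notna()]
            raise DataError(f"non-weed taxa with attribute code: {list(extra)}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def weed_taxa(self, classifiable_only: bool = False) -> list:
        """Taxa categorised as weeds, optionally only those with a valid code."""
        mask = self.item_category == "weed"
        if classifiable_only:
            mask &= self.attribute_code.isin(ATTRIBUTE_CODES)
        return list(self.counts.index[mask])

    def classifiable_weed_totals(self) -> pd.Series:
        """Per-sample totals over weed taxa carrying a valid attribute code."""
        taxa = self.weed_taxa(classifiable_only=True)
        return self.counts.loc[taxa].sum(axis=0)

    def total_items(self) -> pd.Series:
        """Per-sample totals over all taxa."""
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Iterable) -> "CountTable":
        keep = [s for s in self.counts.columns if s in set(sample_ids)]
        return CountTable(
            self.counts[keep], self.item_category.copy(), self.attribute_code.copy()
        )

    def drop_taxa(self, taxa: Iterable) -> "CountTable":
        """Remove the named taxa; absent names are warned about, not fatal."""
        taxa = list(taxa)
        absent = [t for t in taxa if t not in self.counts.index]
        if absent:
            logger.warning("taxa not present in table (ignored): %s", absent)
        keep = self.counts.index.difference(taxa, sort=False)
        return CountTable(
            self.counts.loc[keep],
            self.item_category.loc[keep],
            self.attribute_code.loc[keep],
        )


@dataclass
class TriplotTable:
    """Per-sample grain, rachis and weed-seed totals (Table-of-three layout)."""

    totals: pd.DataFrame

    def __post_init__(self) -> None:
        cols = [c.strip().lower() for c in self.totals.columns]
        if cols != list(_TRIPLOT_COLUMNS):
            raise ConfigurationError(
                f"triplot table must have columns {_TRIPLOT_COLUMNS}, got "
                f"{list(self.totals.columns)}"
            )
        self.totals = self.totals.set_axis(list(_TRIPLOT_COLUMNS), axis=1)
        if (self.totals.to_numpy() < 0).any():
            raise DataError("triplot totals must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.totals.index)

    def total_items(self) -> pd.Series:
        return self.totals.sum(axis=1)


@dataclass(frozen=True)
class DominanceLabel:
    """Crop-dominance label for a sample under a fixed threshold."""

    label: str
    threshold: float = 0.80


def read_counts(
    path: str | Path,
    code_column: str,
    first_sample_column: str,
    category_column: str | None = None,
    samples_as_rows: bool = False,
) -> CountTable:
    """Read a taxon x sample count CSV into a :class:`CountTable`.

    The first column holds taxon identifiers.  Columns before
    ``first_sample_column`` are metadata; ``code_column`` holds the
    weed-seed attribute codes (blank or unrecognised entries become
    :data:`UNCLASSIFIED` with a logged warning) and the optional
    ``category_column`` holds item categories (all taxa default to
    ``weed`` when absent).  Blank count cells read as zero.

    Parameters
    ----------
    path
        CSV file, UTF-8, comma separated, header row present.
    code_column
        Name of the column containing the seed attribute codes.
    first_sample_column
        Name of the first sample column; every column from here to the
        end of the row is a sample.
    category_column
        Optional column naming each taxon's item category.
    samples_as_rows
        If true the file is transposed before parsing (samples as rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if samples_as_rows:
        frame = frame.T
    for name in [code_column, first_sample_column] + (
        [category_column] if category_column else []
    ):
        if name not in frame.columns:
            raise ConfigurationError(
                f"column {name!r} not found in {path.name}; "
                f"available: {list(frame.columns)}"
            )
    start = frame.columns.get_loc(first_sample_column)
    meta = {code_column, category_column}
    sample_cols = [c for c in frame.columns[start:] if c not in meta]
    if not sample_cols:
        raise ConfigurationError("no sample columns after first_sample_column")

    raw = frame[sample_cols].replace("", "0")
    try:
        counts = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in sample_cols:
            for taxon, cell in raw[col].items():
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"non-numeric count {cell!r} at taxon {taxon!r}, "
                        f"sample {col!r}"
                    ) from None
        raise

    codes = frame[code_column].map(_normalise_code)
    if category_column is not None:
        category = frame[category_column].str.strip().str.lower()
        category = category.replace({"": "other", "n": "other", "weeds": "weed"})
    else:
        category = pd.Series("weed", index=frame.index)
    codes = codes.where(category == "weed", other=pd.NA)

    table = CountTable(counts, category, codes)
    n_unclass = sum(
        1
        for t in table.weed_taxa()
        if table.attribute_code[t] == UNCLASSIFIED
    )
    logger.info(
        "read %d taxa x %d samples from %s (%d unclassified weed taxa)",
        len(table.taxon_ids), table.n_samples, path.name, n_unclass,
    )
    return table


def read_triplot(path: str | Path, samples_as_rows: bool = True) -> TriplotTable:
    """Read a per-sample grain/rachis/weeds totals CSV."""
    frame = pd.read_csv(path, index_col=0)
    if not samples_as_rows:
        frame = frame.T
    return TriplotTable(frame)


def filter_min_items(
    table: CountTable | TriplotTable,
    threshold: int,
    basis: str = "total_items",
) -> tuple[CountTable | TriplotTable, list]:
    """Drop samples whose basis count falls below ``threshold``.

    ``basis`` is ``total_items`` (all counted items) or
    ``classifiable_weed_seeds`` (weed taxa with a valid attribute
    code; count tables only).  Sample order is preserved and the
    dropped ids are returned and logged.
    """
    if threshold < 1:
        raise ConfigurationError("threshold must be >= 1")
    if basis == "total_items":
        totals = table.total_items()
    elif basis == "classifiable_weed_seeds":
        if not isinstance(table, CountTable):
            raise ConfigurationError(
                "basis 'classifiable_weed_seeds' requires a CountTable"
            )
        totals = table.classifiable_weed_totals()
    else:
        raise ConfigurationError(f"unknown basis {basis!r}")

    keep = totals[totals >= threshold].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.info(
            "filter_min_items(threshold=%d, basis=%s) dropped %d samples: %s",
            threshold, basis, len(dropped), dropped,
        )
    if isinstance(table, CountTable):
        return table.select_samples(keep), dropped
    return TriplotTable(table.totals.loc[[s for s in table.sample_ids if s in set(keep)]]), dropped


def classify_dominance(
    table: CountTable,
    crop_groups: Mapping[str, Iterable],
    threshold: float = 0.80,
    pulse_groups: Iterable[str] = (),
    union_label: str = "free-threshing cereal",
    union_members: tuple[str, str] = ("wheat", "barley"),
) -> dict:
    """Label each sample by the crop that dominates its crop items.

    The denominator is crop items only (taxa listed in
    ``crop_groups``); weeds and other material are excluded.  A sample
    is labelled with the unique crop group whose share reaches
    ``threshold``; failing that, the union of the two
    ``union_members`` groups is evaluated under ``union_label`` (the
    free-threshing cereal rule); otherwise the sample is ``mixed``.
    Pulse groups are reported as ``pulse-<name>``.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must be in (0, 1]")
    pulse_groups = set(pulse_groups)
    group_taxa = {
        name: [t for t in taxa if t in table.counts.index]
        for name, taxa in crop_groups.items()
    }
    labels: dict = {}
    for sample in table.sample_ids:
        col = table.counts[sample]
        group_items = {g: int(col.loc[taxa].sum()) for g, taxa in group_taxa.items()}
        total = sum(group_items.values())
        if total == 0:
            logger.warning("sample %r has zero crop items; labelled mixed", sample)
            labels[sample] = DominanceLabel("mixed", threshold)
            continue
        label = "mixed"
        for name, items in group_items.items():
            if items / total >= threshold:
                label = f"pulse-{name}" if name in pulse_groups else name
                break
        else:
            a, b = union_members
            union = group_items.get(a, 0) + group_items.get(b, 0)
            if union / total >= threshold:
                label = union_label
        labels[sample] = DominanceLabel(label, threshold)
    return labels


def write_results(result, path: str | Path) -> Path:
    """Write a classification result to CSV.

    One row per sample with its class, per-group posteriors and
    discriminant scores; the classification table goes to a companion
    file ``<stem>_table.csv``.  Returns the main path.
    """
    from cropsift.classify import classification_table  # circular at import time

    path = Path(path)
    frame = result.to_frame()
    if frame.empty:
        # header-only file for an empty result
        frame.to_csv(path, index_label="sample")
        return path
    frame.to_csv(path, index_label="sample", float_format="%.10g")
    table = classification_table(result)
    table.to_csv(path.with_name(path.stem + "_table.csv"), index_label="class")
    logger.info("wrote %d classified samples to %s", len(frame), path)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back the per-sample frame written by :func:`write_results`."""
    return pd.read_csv(path, index_col="sample")
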