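"""Square-root percentage attribute transform.

Each classifiable weed taxon contributes the square root of its
percentage of the sample's classifiable weed seeds; contributions are
summed per attribute code, giving a samples x 6 score matrix.  Note
the order of operations: roots are taken per taxon and then summed
(sum-of-roots), which is not the same as the root of the summed
percentage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cropsift.io import ATTRIBUTE_CODES, UNCLASSIFIED, CountTable, DataError

logger = logging.getLogger(__name__)


def drop_unclassified(table: CountTable) -> CountTable:
    """Remove unclassifiable weed taxa and all non-weed rows.

    Removed taxa are logged so the cleaning step is auditable.  A
    table with nothing to remove is returned with only weed rows.
    """
    is_weed = table.item_category == "weed"
    coded = table.attribute_code.isin(ATTRIBUTE_CODES)
    keep = table.counts.index[is_weed & coded]
    removed = [t for t in table.taxon_ids if t not in set(keep)]
    if removed:
        logger.info("drop_unclassified removed %d taxa: %s", len(removed), removed)
    return CountTable(
        table.counts.loc[keep],
        table.item_category.loc[keep],
        table.attribute_code.loc[keep],
    )


def attribute_transform(table: CountTable) -> pd.DataFrame:
    """Convert weed-seed counts to the six-attribute score matrix.

    For sample ``s`` with classifiable-weed total ``N_s``, taxon ``i``
    contributes ``sqrt(100 * n_is / N_s)`` to the column of its
    attribute code.  Returns a DataFrame with samples as rows and the
    six code columns in canonical order.

    Raises
    ------
    DataError
        If any sample has no classifiable weed seeds — filter such
        samples out first (:func:`cropsift.io.filter_min_items` with
        basis ``classifiable_weed_seeds``).
    """
    taxa = table.weed_taxa(classifiable_only=True)
    counts = table.counts.loc[taxa]
    totals = counts.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise DataError(
            f"samples with no classifiable weed seeds: {empty}; "
            "apply filter_min_items(basis='classifiable_weed_seeds') first"
        )
    if (table.attribute_code.loc[table.weed_taxa()] == UNCLASSIFIED).any():
        logger.debug("unclassified weed taxa present; they are ignored")

    pct = 100.0 * counts.div(totals, axis=1)
    roots = np.sqrt(pct)
    codes = table.attribute_code.loc[taxa]
    scores = roots.groupby(codes, sort=False).sum().T
    scores = scores.reindex(columns=list(ATTRIBUTE_CODES), fill_value=0.0)
    scores.index.name = "sample"
    return scores
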