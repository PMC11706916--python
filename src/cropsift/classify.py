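"""The two classification procedures and their summary tables.

``jones_classify`` fits the four-group model on the ethnographic
reference alone and classifies archaeological samples among the four
crop-processing stages.  ``charles_classify`` refits with the
archaeological samples included as a fifth group and reclassifies
them among the five, to test whether they resemble crop processing at
all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cropsift.io import ATTRIBUTE_CODES, CountTable, filter_min_items
from cropsift.lda import LdaModel, fit_lda, posterior, predict_class, project
from cropsift.transform import attribute_transform, drop_unclassified

logger = logging.getLogger(__name__)

#: Canonical group numbering and names.
GROUP_NAMES = {
    1: "winnowing by-product",
    2: "coarse sieve by-product",
    3: "fine sieve by-product",
    4: "fine sieve product",
    5: "archaeological",
}

ARCH_GROUP = 5


def _check_attribute_matrix(X: pd.DataFrame, what: str) -> pd.DataFrame:
    missing = [c for c in ATTRIBUTE_CODES if c not in X.columns]
    if missing:
        raise ValueError(f"{what} is missing attribute columns {missing}")
    return X[list(ATTRIBUTE_CODES)].astype(float)


@dataclass
class ReferenceSet:
    """Ethnographic attribute scores with group labels 1-4."""

    scores: pd.DataFrame
    groups: pd.Series
    name: str = "ethnographic reference"

    def __post_init__(self) -> None:
        self.scores = _check_attribute_matrix(self.scores, "reference")
        self.groups = pd.Series(self.groups, index=self.scores.index).astype(int)
        present = sorted(self.groups.unique())
        if present != [1, 2, 3, 4]:
            raise ValueError(f"reference must contain groups 1-4, got {present}")
        sizes = self.groups.value_counts()
        if (sizes < 2).any():
            raise ValueError("every reference group needs at least 2 samples")

    @classmethod
    def from_csv(cls, path, group_column: str = "Group", **kwargs) -> "ReferenceSet":
        frame = pd.read_csv(path, index_col=0)
        if group_column not in frame.columns:
            raise ValueError(f"group column {group_column!r} not in {path}")
        groups = frame[group_column]
        return cls(frame.drop(columns=[group_column]), groups, **kwargs)

    def to_csv(self, path, group_column: str = "Group") -> None:
        frame = self.scores.copy()
        frame[group_column] = self.groups
        frame.to_csv(path, index_label="sample")


@dataclass
class ClassificationResult:
    """Per-sample classes, posteriors and scores plus the fitted model.

    ``ref_scores``/``ref_groups`` carry the reference samples'
    coordinates under *this* model so plots never mix coordinate
    systems between the two methods.
    """

    classes: pd.Series
    posteriors: pd.DataFrame
    scores: pd.DataFrame
    model: LdaModel
    method: str
    ref_scores: pd.DataFrame
    ref_groups: pd.Series

    @property
    def sample_ids(self) -> list:
        return list(self.classes.index)

    def to_frame(self) -> pd.DataFrame:
        """One row per sample: class, posteriors, discriminant scores."""
        post = self.posteriors.rename(columns=lambda g: f"prob_{g}")
        return pd.concat([self.classes.rename("class"), post, self.scores], axis=1)


def _result(model, arch, reference_X, reference_groups, method) -> ClassificationResult:
    return ClassificationResult(
        classes=predict_class(model, arch),
        posteriors=posterior(model, arch),
        scores=project(model, arch),
        model=model,
        method=method,
        ref_scores=project(model, reference_X),
        ref_groups=pd.Series(reference_groups, index=reference_X.index).astype(int),
    )


def jones_classify(
    reference: ReferenceSet, arch: pd.DataFrame, priors="proportional"
) -> ClassificationResult:
    """Classify archaeological samples against the four-group model.

    The model is fitted on the ethnographic reference only (G = 4,
    three discriminant functions); the archaeological attribute matrix
    is then scored, given posteriors and assigned the most probable
    crop-processing stage.
    """
    arch = _check_attribute_matrix(arch, "archaeological data")
    model = fit_lda(reference.scores, reference.groups, priors=priors)
    return _result(model, arch, reference.scores, reference.groups, "jones")


def charles_classify(
    reference: ReferenceSet, arch: pd.DataFrame, priors="proportional"
) -> ClassificationResult:
    """Reclassify archaeological samples with themselves as a fifth group.

    The model is fitted on reference plus archaeological samples
    labelled group 5 (G = 5, four discriminant functions); the same
    archaeological samples are then re-entered and classified among
    the five groups.
    """
    arch = _check_attribute_matrix(arch, "archaeological data")
    if len(arch) < 2:
        raise ValueError(
            "the archaeological set needs at least 2 samples to form a group"
        )
    overlap = set(arch.index) & set(reference.scores.index)
    if overlap:
        arch = arch.rename(index={s: f"{s} (arch)" for s in overlap})
    X = pd.concat([reference.scores, arch])
    groups = pd.concat(
        [reference.groups, pd.Series(ARCH_GROUP, index=arch.index)]
    )
    model = fit_lda(X, groups, priors=priors)
    return _result(model, arch, reference.scores, reference.groups, "charles")


def classification_table(result: ClassificationResult) -> pd.DataFrame:
    """Counts and percentages of samples per class.

    Every group of the model appears, including zero-count classes;
    percentages are of the number of classified samples and sum to
    100 (up to rounding).
    """
    if len(result.classes) == 0:
        raise ValueError("empty classification result")
    counts = result.classes.value_counts().reindex(
        result.model.group_labels, fill_value=0
    )
    n = int(counts.sum())
    table = pd.DataFrame(
        {
            "name": [GROUP_NAMES.get(g, str(g)) for g in counts.index],
            "count": counts.to_numpy(),
            "percentage": 100.0 * counts.to_numpy() / n,
        },
        index=pd.Index(counts.index, name="class"),
    )
    return table


def format_classification_table(result: ClassificationResult) -> str:
    """Aligned plain-text rendering of the classification table."""
    table = classification_table(result)
    width = max(len(str(v)) for v in table["name"]) + 2
    lines = ["Classification table", "-" * (width + 22)]
    for cls, row in table.iterrows():
        lines.append(
            f"{cls}  {row['name']:<{width}}{int(row['count']):>5}"
            f"{row['percentage']:>10.1f}%"
        )
    lines.append(f"   {'total':<{width}}{int(table['count'].sum()):>5}{100.0:>10.1f}%")
    return "\n".join(lines)


def run_pipeline(
    table: CountTable,
    reference: ReferenceSet,
    method: str = "jones",
    min_seeds: int = 10,
    priors="proportional",
) -> ClassificationResult:
    """Counts -> clean -> filter -> transform -> classify, in one call."""
    cleaned = drop_unclassified(table)
    kept, _ = filter_min_items(cleaned, min_seeds, basis="classifiable_weed_seeds")
    arch = attribute_transform(kept)
    if method == "jones":
        return jones_classify(reference, arch, priors=priors)
    if method == "charles":
        return charles_classify(reference, arch, priors=priors)
    raise ValueError(f"unknown method {method!r}")


def rerun_without_taxa(
    table: CountTable,
    taxa_to_remove,
    reference: ReferenceSet,
    method: str = "jones",
    min_seeds: int = 10,
    priors="proportional",
) -> tuple[ClassificationResult, ClassificationResult, pd.DataFrame]:
    """Re-run the pipeline after removing taxa and report class changes.

    The minimum-seed filter is re-applied after removal, so sample
    membership may shrink; samples present in only one run appear in
    the report with a missing class on the other side.

    Returns
    -------
    (before, after, changes)
        ``changes`` has columns ``class_before``, ``class_after`` and
        boolean ``changed`` (NA classes count as changed only if the
        sample exists on the other side).
    """
    before = run_pipeline(table, reference, method, min_seeds, priors)
    after = run_pipeline(
        table.drop_taxa(taxa_to_remove), reference, method, min_seeds, priors
    )
    all_ids = list(
        dict.fromkeys(list(before.classes.index) + list(after.classes.index))
    )
    changes = pd.DataFrame(
        {
            "class_before": before.classes.reindex(all_ids),
            "class_after": after.classes.reindex(all_ids),
        }
    )
    both = changes.notna().all(axis=1)
    changes["changed"] = False
    changes.loc[both, "changed"] = (
        changes.loc[both, "class_before"] != changes.loc[both, "class_after"]
    )
    n_changed = int(changes["changed"].sum())
    logger.info(
        "rerun_without_taxa: %d of %d shared samples changed class",
        n_changed, int(both.sum()),
    )
    return before, after, changes
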