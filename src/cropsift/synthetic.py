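"""Synthetic reference sets and archaeological assemblages.

The shipped supplements of the original study cannot be redistributed
here, so this module generates ethnographic-like fixtures that encode
only the qualitative logic of the attribute scheme: winnowing
by-products are enriched in small light seeds, coarse-sieve
by-products in headed seeds, fine-sieve by-products in small free
seeds, and the fine-sieve product in big heavy contaminants.  All
profile values are synthetic parameters, not field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cropsift.io import ATTRIBUTE_CODES, CountTable
from cropsift.classify import ReferenceSet
from cropsift.transform import attribute_transform


@dataclass(frozen=True)
class GroupProfile:
    """Sampling profile for one group of assemblages.

    ``weights`` give the expected compositional share of each
    attribute code; ``expected_seeds`` the mean classifiable-seed
    count per sample; ``concentration`` the Dirichlet concentration
    controlling between-sample overdispersion (larger = tighter).
    """

    label: object
    weights: Mapping[str, float]
    expected_seeds: float = 120.0
    concentration: float = 60.0

    def weight_vector(self) -> np.ndarray:
        w = np.array([float(self.weights.get(c, 0.0)) for c in ATTRIBUTE_CODES])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError(f"profile {self.label!r} needs non-negative weights "
                             "with a positive sum")
        return w / w.sum()


def default_profiles(
    expected_seeds: float = 120.0, concentration: float = 60.0
) -> dict:
    """Well-separated default profiles for the four processing groups."""
    raw = {
        1: {"SFL": 0.50, "SHL": 0.30, "SFH": 0.10, "SHH": 0.05, "BHH": 0.03, "BFH": 0.02},
        2: {"BHH": 0.45, "SHH": 0.35, "SHL": 0.10, "BFH": 0.05, "SFH": 0.03, "SFL": 0.02},
        3: {"SFH": 0.45, "SFL": 0.35, "SHH": 0.08, "SHL": 0.07, "BFH": 0.03, "BHH": 0.02},
        4: {"BFH": 0.55, "BHH": 0.30, "SFH": 0.08, "SHH": 0.04, "SFL": 0.02, "SHL": 0.01},
    }
    return {
        g: GroupProfile(g, w, expected_seeds, concentration) for g, w in raw.items()
    }


#: A composition dissimilar to all four processing groups, standing in
#: for material with a non-crop-processing origin (e.g. dung-derived).
CONTAMINATION_PROFILE = GroupProfile(
    "contamination",
    {"BHH": 1, "BFH": 1, "SHH": 1, "SHL": 1, "SFH": 1, "SFL": 1},
)


def _taxon_layout(taxa_per_code: int) -> tuple[list, np.ndarray]:
    """Taxon ids and their code index, ``taxa_per_code`` per code."""
    ids, code_idx = [], []
    for j, code in enumerate(ATTRIBUTE_CODES):
        for k in range(taxa_per_code):
            ids.append(f"{code.lower()}_taxon_{k + 1}")
            code_idx.append(j)
    return ids, np.array(code_idx)


def _sample_counts(
    rng: np.random.Generator,
    profile: GroupProfile,
    n_samples: int,
    taxa_per_code: int,
    compound: bool,
) -> np.ndarray:
    """Draw a taxa x samples count block from one profile."""
    code_w = profile.weight_vector()
    _, code_idx = _taxon_layout(taxa_per_code)
    taxon_w = code_w[code_idx] / taxa_per_code
    n_taxa = len(code_idx)
    out = np.zeros((n_taxa, n_samples), dtype=int)
    alpha = np.maximum(taxon_w * profile.concentration, 1e-6)
    for s in range(n_samples):
        p = rng.dirichlet(alpha) if compound else taxon_w
        total = rng.poisson(profile.expected_seeds)
        if total > 0:
            out[:, s] = rng.multinomial(total, p)
    return out


def _as_count_table(block: np.ndarray, taxa_per_code: int, sample_ids) -> CountTable:
    ids, code_idx = _taxon_layout(taxa_per_code)
    counts = pd.DataFrame(block, index=ids, columns=list(sample_ids))
    category = pd.Series("weed", index=counts.index)
    codes = pd.Series([ATTRIBUTE_CODES[j] for j in code_idx], index=counts.index)
    return CountTable(counts, category, codes)


def generate_reference(
    profiles: Mapping[int, GroupProfile] | None = None,
    n_per_group: int = 10,
    seed: int = 0,
    taxa_per_code: int = 2,
    compound: bool = True,
) -> tuple[CountTable, pd.Series]:
    """Generate an ethnographic-like reference count table.

    Per sample a taxon-level composition is drawn from the group's
    Dirichlet (compound multinomial; set ``compound=False`` for a
    plain multinomial) and integer counts are drawn at a Poisson
    total.  Returns the table and the group label per sample.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    blocks, sample_ids, labels = [], [], []
    for g in sorted(profiles):
        prof = profiles[g]
        blocks.append(_sample_counts(rng, prof, n_per_group, taxa_per_code, compound))
        sample_ids += [f"eth_g{g}_{i + 1}" for i in range(n_per_group)]
        labels += [g] * n_per_group
    table = _as_count_table(np.hstack(blocks), taxa_per_code, sample_ids)
    return table, pd.Series(labels, index=sample_ids, name="group")


def generate_archaeological(
    stage_mixture: Mapping[int, float],
    n: int = 20,
    seed: int = 0,
    contamination: float = 0.0,
    contamination_profile: GroupProfile = CONTAMINATION_PROFILE,
    profiles: Mapping[int, GroupProfile] | None = None,
    taxa_per_code: int = 2,
    compound: bool = True,
) -> CountTable:
    """Generate archaeological samples from a mixture of stage profiles.

    Each sample's code weights are the ``stage_mixture``-weighted
    blend of the group profiles, further blended with
    ``contamination_profile`` at fraction ``contamination`` (an
    off-manifold component standing in for non-crop-processing
    input).  ``n = 0`` yields an empty table.
    """
    weights = np.array([stage_mixture.get(g, 0.0) for g in (1, 2, 3, 4)], float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("stage_mixture weights must be non-negative and sum to 1")
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be in [0, 1]")
    profiles = profiles or default_profiles()
    base = sum(
        w * profiles[g].weight_vector() for g, w in zip((1, 2, 3, 4), weights)
    )
    blend = (1 - contamination) * base + contamination * (
        contamination_profile.weight_vector()
    )
    ref_prof = profiles[max(stage_mixture, key=stage_mixture.get)]
    prof = GroupProfile(
        "archaeological",
        dict(zip(ATTRIBUTE_CODES, blend)),
        ref_prof.expected_seeds,
        ref_prof.concentration,
    )
    rng = np.random.default_rng(seed)
    block = _sample_counts(rng, prof, n, taxa_per_code, compound)
    return _as_count_table(block, taxa_per_code, [f"arch_{i + 1}" for i in range(n)])


def synthetic_reference_set(
    seed: int = 0, n_per_group: int = 10, **kwargs
) -> ReferenceSet:
    """A ready-to-use synthetic :class:`~cropsift.classify.ReferenceSet`."""
    table, groups = generate_reference(n_per_group=n_per_group, seed=seed, **kwargs)
    return ReferenceSet(
        attribute_transform(table), groups, name="synthetic reference"
    )


def generate_reference_triplot(seed: int = 0, n_per_group: int = 10):
    """Synthetic ethnographic grain/rachis/weeds totals per group.

    Group compositions follow the qualitative expectations: the
    cleaned product is grain-rich; early by-products are poor in
    grain and rich in rachis and weed seeds.
    """
    from cropsift.io import TriplotTable

    comps = {
        1: (0.10, 0.30, 0.60),  # winnowing by-product: light chaff and weeds
        2: (0.15, 0.55, 0.30),  # coarse sieve by-product: rachis rich
        3: (0.10, 0.15, 0.75),  # fine sieve by-product: small weed seeds
        4: (0.85, 0.05, 0.10),  # fine sieve product: cleaned grain
    }
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], []
    for g, comp in comps.items():
        alpha = np.array(comp) * 40
        for i in range(n_per_group):
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(rng.poisson(500), p))
            ids.append(f"eth_g{g}_{i + 1}")
            labels.append(g)
    totals = pd.DataFrame(rows, index=ids, columns=["grain", "rachis", "weeds"])
    return TriplotTable(totals), pd.Series(labels, index=ids, name="group")
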