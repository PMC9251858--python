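"""Per-BTU sample x sample dissimilarities on proportion-transformed counts.

Counts are divided by the *whole-sample* library size before any BTU
subsetting, so a BTU-restricted row sums to the BTU's share of the library
rather than to 1 (no within-BTU renormalization by default; pass
``renormalize=True`` to `btu_proportions` for sensitivity analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import EmptyDatasetError, UntestableError


def to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its library size.  Zero-library rows are an error."""
    lib = counts.sum(axis=1)
    zero = lib.index[lib == 0]
    if len(zero):
        raise EmptyDatasetError(f"samples with zero library size: {list(zero)[:10]}")
    return counts.div(lib, axis=0)


def btu_sample_subset(counts: pd.DataFrame, asv_subset) -> list:
    """Samples hosting the BTU: at least one read summed over its ASVs."""
    asvs = [a for a in asv_subset if a in counts.columns]
    if not asvs:
        raise ValueError("BTU has no ASVs present in the count table")
    mask = counts[asvs].sum(axis=1) > 0
    return list(counts.index[mask])


def check_testable(hosting_samples, species_of_sample: pd.Series,
                   min_samples: int = 3, min_species: int = 2) -> None:
    """Raise UntestableError when too few hosting samples or species."""
    n = len(hosting_samples)
    k = species_of_sample.loc[hosting_samples].nunique() if n else 0
    if n < min_samples or k < min_species:
        raise UntestableError(
            f"only {n} hosting samples across {k} species")


def btu_proportions(props: pd.DataFrame, sample_subset, asv_subset,
                    renormalize: bool = False) -> pd.DataFrame:
    sub = props.loc[list(sample_subset), list(asv_subset)]
    if renormalize:
        tot = sub.sum(axis=1)
        sub = sub.div(tot.where(tot > 0, 1.0), axis=0)
    return sub


def bray_curtis(props: pd.DataFrame, sample_subset, asv_subset) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, BC(x,y) = 1 - 2 sum(min) / sum(x + y)."""
    sub = btu_proportions(props, sample_subset, asv_subset)
    if sub.shape[0] < 2:
        raise UntestableError("need >= 2 samples for a dissimilarity matrix")
    if (sub.sum(axis=1) == 0).any():
        raise UntestableError("all-zero rows make Bray-Curtis undefined")
    d = squareform(pdist(sub.values, metric="braycurtis"))
    return DistanceMatrix(d, list(sub.index))


def jaccard_binary(props: pd.DataFrame, sample_subset, asv_subset) -> DistanceMatrix:
    """Binary Jaccard: 1 - |support intersection| / |support union|."""
    sub = btu_proportions(props, sample_subset, asv_subset)
    if sub.shape[0] < 2:
        raise UntestableError("need >= 2 samples for a dissimilarity matrix")
    pres = sub.values > 0
    if (~pres.any(axis=1)).any():
        raise UntestableError("all-zero rows make Jaccard undefined")
    d = squareform(pdist(pres, metric="jaccard"))
    return DistanceMatrix(d, list(sub.index))
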