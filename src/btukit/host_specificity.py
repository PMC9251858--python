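"""PERMANOVA-based host-species specificity of BTU composition.

The statistic follows the distance-matrix formulation: with the Gower-centered
matrix G = -1/2 C D^2 C and the hat matrix H of the one-factor species model
(k levels over n samples),

    SS_total = tr(G),   SS_model = tr(H G H),
    F  = [SS_model / (k-1)] / [(SS_total - SS_model) / (n-k)],
    R2 = SS_model / SS_total,

and significance comes from unrestricted random relabeling of samples.  For
cross-BTU comparability the adjusted coefficient

    R2adj = 1 - (1 - R2) (n - 1) / (n - k)

corrects R2 for the differing numbers of hosting samples and species.
Computation uses the equivalent group-sum identities on D^2 (no explicit
projection matrices), which also makes the permutation loop a single batched
matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import UntestableError

__all__ = ["PermanovaResult", "permanova", "permanova_statistics",
           "adjusted_r2", "subset_specificity_test"]


@dataclass
class PermanovaResult:
    btu: str
    pseudo_f: float
    r2: float
    r2adj: float
    p: float
    n_samples: int
    n_species: int
    n_perm: int
    q: float | None = None


def _codes(labels) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(labels))
    return codes


def _ss_stats(d2: np.ndarray, codes: np.ndarray, k: int):
    """(ss_total, ss_model) via within-group sums of squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_total, ss_total - ss_within


def permanova_statistics(dist: DistanceMatrix, labels):
    """(pseudo_F, R2, SS_total, SS_model) for one labeling; no permutations."""
    codes = _codes(labels)
    k = codes.max() + 1
    n = len(codes)
    if k < 2:
        raise UntestableError("PERMANOVA needs >= 2 species")
    if n <= k:
        raise UntestableError("PERMANOVA needs n > k samples")
    d2 = dist.data**2
    ss_total, ss_model = _ss_stats(d2, codes, k)
    if ss_total <= 0:
        raise UntestableError("zero total sum of squares")
    with np.errstate(divide="ignore"):
        f = (ss_model / (k - 1)) / ((ss_total - ss_model) / (n - k))
    return f, ss_model / ss_total, ss_total, ss_model


def _batched_f(d2: np.ndarray, code_mat: np.ndarray, k: int) -> np.ndarray:
    """Pseudo-F for many labelings at once.

    code_mat: (P, n) integer species codes per permutation.
    """
    P, n = code_mat.shape
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    # one-hot blocks: columns (P*k), scaled by 1/n_g
    fs = np.empty(P)
    chunk = max(1, int(4e6 // (n * k)))
    for start in range(0, P, chunk):
        block = code_mat[start:start + chunk]
        B = block.shape[0]
        Z = np.zeros((n, B * k))
        for b in range(B):
            Z[np.arange(n), b * k + block[b]] = 1.0
        M = d2 @ Z  # n x (B*k)
        sw = np.empty(B)
        for b in range(B):
            zb = Z[:, b * k:(b + 1) * k]
            ng = zb.sum(axis=0)
            num = np.einsum("ij,ij->j", zb, M[:, b * k:(b + 1) * k])
            sw[b] = 0.5 * np.sum(num[ng > 0] / ng[ng > 0])
        ss_model = ss_total - sw
        # a permuted labeling with zero residual SS legitimately yields +inf
        with np.errstate(divide="ignore", invalid="ignore"):
            fs[start:start + B] = (ss_model / (k - 1)) / ((ss_total - ss_model) / (n - k))
    return fs


def permanova(dist: DistanceMatrix, species_labels, n_perm: int = 10000,
              seed: int = 0, btu: str = "") -> PermanovaResult:
    """One-factor PERMANOVA of a sample dissimilarity matrix on species identity.

    ``species_labels`` may be a sequence aligned with ``dist.ids`` or a
    mapping/Series from sample ID to species.
    """
    if isinstance(species_labels, (dict, pd.Series)):
        labels = [species_labels[i] for i in dist.ids]
    else:
        labels = list(species_labels)
    codes = _codes(labels)
    k = int(codes.max() + 1)
    n = len(codes)
    f_obs, r2, _, _ = permanova_statistics(dist, labels)
    d2 = dist.data**2

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=codes.dtype)
    for p in range(n_perm):
        perms[p] = codes[rng.permutation(n)]
    f_perm = _batched_f(d2, perms, k)
    p_val = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)

    return PermanovaResult(
        btu=btu, pseudo_f=float(f_obs), r2=float(r2),
        r2adj=float(adjusted_r2(r2, n, k)), p=float(p_val),
        n_samples=n, n_species=k, n_perm=n_perm)


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Degrees-of-freedom-corrected R2 for a one-factor model (may be < 0)."""
    if n <= k or k < 2:
        raise UntestableError(f"adjusted R2 undefined for n={n}, k={k}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)


def subset_specificity_test(dist_builder, full_asv_set, target_asv_subset,
                            species_labels, n_perm: int = 9999, seed: int = 0):
    """Is the target ASV subset more host-specific than random subsets?

    ``dist_builder(asv_ids)`` must return a DistanceMatrix over the samples
    hosting those ASVs.  The observed statistic is the PERMANOVA R2adj of the
    target subset; the null redraws ``len(target)`` ASVs uniformly without
    replacement from ``full_asv_set`` and repeats the computation.

    Returns (r2adj_observed, p).
    """
    full = list(full_asv_set)
    target = list(target_asv_subset)
    if len(target) > len(full):
        raise ValueError("target subset larger than the full ASV set")
    if len(target) < 2:
        raise ValueError("target subset needs >= 2 ASVs")
    if not set(target) <= set(full):
        raise ValueError("target subset must be contained in the full ASV set")

    def stat(asvs) -> float:
        dm = dist_builder(asvs)
        labels = [species_labels[i] for i in dm.ids]
        _, r2, _, _ = permanova_statistics(dm, labels)
        return adjusted_r2(r2, len(dm.ids), len(set(labels)))

    obs = stat(target)
    rng = np.random.default_rng(seed)
    full_arr = np.array(full)
    hits = 0
    for _ in range(n_perm):
        draw = full_arr[rng.choice(len(full_arr), size=len(target), replace=False)]
        if stat(list(draw)) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(obs), float(p)
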