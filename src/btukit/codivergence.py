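"""Procrustean co-divergence of microbiota and host phylogeny (PACo style).

Two flavors are computed per BTU.  Compositional co-divergence (P_COMP)
superimposes the PCoA embedding of sample-level community dissimilarities on
the PCoA embedding of host cophenetic distances lifted to the sample level
(distance 0 between samples of the same species).  Phylogenetic co-divergence
(P_PHYLO) superimposes ASV genetic-distance embeddings on the host embedding
through the ASV x sample occurrence list, one stacked row per occurrence.

Both use symmetric Procrustes: each configuration is column-centered and
scaled to unit total sum of squares, the optimal rotation comes from the SVD
of X'Y, and the residual sum of squares m^2 = 1 - (sum of singular values)^2
yields the Procrustes correlation r = sqrt(1 - m^2).

Significance uses a species-block permutation: species identities are
reshuffled across intact blocks of same-species samples, the host-side
configuration is rebuilt, and the observed m^2 is compared against the
permuted ones (small m^2 = congruent).  For balanced designs the permuted
host-side matrix is a row/column permutation of the observed one, so the null
reuses the observed embedding's per-species coordinates; ``exact_perm=True``
recomputes the embedding each round instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from skbio import DistanceMatrix

from .btu_binning import mismatch_fractions
from .errors import UntestableError

logger = logging.getLogger(__name__)

__all__ = [
    "Configuration", "PacoResult", "pcoa", "procrustes_fit", "procrustes_m2",
    "block_permute", "sample_level_host_distances", "paco_compositional",
    "genetic_distances", "paco_phylogenetic", "mantel",
]

#: relative eigenvalue floor below which PCoA axes are discarded
_EIG_RTOL = 1e-8


@dataclass
class Configuration:
    """A PCoA embedding: items x axes coordinates, axes by decreasing eigenvalue."""

    ids: list
    coords: np.ndarray
    eigenvalues: np.ndarray
    min_eigenvalue: float = 0.0  # most negative raw eigenvalue (0 if none)


@dataclass
class PacoResult:
    btu: str
    m2: float
    r: float
    p: float
    mode: str  # "COMP" or "PHYLO"
    n_perm: int
    n_items: int
    q: float | None = None


def pcoa(dist: DistanceMatrix) -> Configuration:
    """Principal coordinates of a distance matrix (Gower double-centering).

    Axes with eigenvalue <= 1e-8 * max eigenvalue (including all negative
    ones) are dropped; the most negative raw eigenvalue is recorded so
    callers can log non-Euclidean inputs.
    """
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n = d2.shape[0]
    if n < 2:
        raise UntestableError("PCoA needs >= 2 items")
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    g = -0.5 * (d2 - row - col + d2.mean())
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    min_eig = float(min(evals.min(), 0.0))
    if min_eig < -1e-8:
        logger.debug("PCoA: non-Euclidean input, most negative eigenvalue %.3g", min_eig)
    keep = evals > max(evals.max(), 0.0) * _EIG_RTOL
    keep &= evals > 0
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return Configuration(ids=list(dist.ids), coords=coords,
                         eigenvalues=evals[keep], min_eigenvalue=min_eig)


def _center_scale(mat: np.ndarray) -> np.ndarray:
    c = mat - mat.mean(axis=0, keepdims=True)
    norm = np.sqrt((c**2).sum())
    if norm <= 0:
        raise UntestableError("degenerate (zero-variance) configuration")
    return c / norm


def procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual sum of squares of two row-matched matrices.

    Columns need not agree: the singular values of X'Y are unchanged by
    zero-padding the narrower matrix, so none is applied.
    """
    if x.shape[0] != y.shape[0]:
        raise ValueError("row counts must match")
    if x.shape[0] < 3:
        raise UntestableError("need >= 3 stacked rows for Procrustes")
    xs = _center_scale(x)
    ys = _center_scale(y)
    sv = np.linalg.svd(xs.T @ ys, compute_uv=False)
    m2 = 1.0 - float(sv.sum()) ** 2
    return float(min(max(m2, 0.0), 1.0))


def procrustes_fit(x: Configuration, y: Configuration, row_pairs) -> tuple:
    """(m2, r) after stacking configuration rows per (x_id, y_id) pair."""
    xi = {i: k for k, i in enumerate(x.ids)}
    yi = {i: k for k, i in enumerate(y.ids)}
    rows_x = np.array([xi[a] for a, _ in row_pairs])
    rows_y = np.array([yi[b] for _, b in row_pairs])
    m2 = procrustes_m2(x.coords[rows_x], y.coords[rows_y])
    return m2, float(np.sqrt(1.0 - m2))


def block_permute(species_of_item, rng: np.random.Generator) -> np.ndarray:
    """Reshuffle species identities across intact same-species blocks.

    Each block of same-species items receives, as a whole, the identity of
    another species drawn from a uniform random permutation of the species
    present.  With one item per species this reduces to an ordinary label
    permutation.
    """
    arr = np.asarray(species_of_item)
    uniq = np.unique(arr)
    if len(uniq) < 2:
        raise UntestableError("block permutation needs >= 2 species")
    perm = rng.permutation(len(uniq))
    mapping = {sp: uniq[perm[i]] for i, sp in enumerate(uniq)}
    return np.array([mapping[sp] for sp in arr])


def sample_level_host_distances(host_coph: DistanceMatrix,
                                species_of_sample: pd.Series) -> DistanceMatrix:
    """Lift species cophenetic distances to samples (0 within species)."""
    samples = list(species_of_sample.index)
    sp_idx = {sp: i for i, sp in enumerate(host_coph.ids)}
    codes = np.array([sp_idx[sp] for sp in species_of_sample.values])
    mat = host_coph.data[np.ix_(codes, codes)].copy()
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, samples)


def _species_representative_coords(config: Configuration,
                                   species_of_sample: pd.Series) -> tuple:
    """Per-species coordinate rows (samples of one species are coincident)."""
    uniq = sorted(set(species_of_sample.values))
    first = {}
    for pos, sid in enumerate(config.ids):
        sp = species_of_sample[sid]
        if sp not in first:
            first[sp] = pos
    reps = np.stack([config.coords[first[sp]] for sp in uniq])
    codes = np.array([uniq.index(species_of_sample[sid]) for sid in config.ids])
    return uniq, reps, codes


def _paco_p(m2_obs: float, m2_perm: np.ndarray, n_perm: int) -> float:
    return (1 + int((m2_perm <= m2_obs + 1e-12).sum())) / (1 + n_perm)


def paco_compositional(gm_dist: DistanceMatrix, host_coph: DistanceMatrix,
                       species_of_sample: pd.Series, n_perm: int = 10000,
                       seed: int = 0, btu: str = "",
                       exact_perm: bool = False) -> PacoResult:
    """Compositional co-divergence: community vs host distances, sample level."""
    samples = list(gm_dist.ids)
    spp = species_of_sample.loc[samples]
    if spp.nunique() < 2:
        raise UntestableError("P_COMP needs >= 2 host species among hosting samples")
    host_sample_dm = sample_level_host_distances(host_coph, spp)
    x = pcoa(host_sample_dm)
    y = pcoa(gm_dist)
    m2_obs = procrustes_m2(x.coords, y.coords)

    rng = np.random.default_rng(seed)
    m2_perm = np.empty(n_perm)
    if exact_perm:
        for i in range(n_perm):
            permuted = pd.Series(block_permute(spp.values, rng), index=spp.index)
            xp = pcoa(sample_level_host_distances(host_coph, permuted))
            m2_perm[i] = procrustes_m2(xp.coords, y.coords)
    else:
        uniq, reps, codes = _species_representative_coords(x, spp)
        for i in range(n_perm):
            perm = rng.permutation(len(uniq))
            m2_perm[i] = procrustes_m2(reps[perm][codes], y.coords)

    p = _paco_p(m2_obs, m2_perm, n_perm)
    return PacoResult(btu=btu, m2=m2_obs, r=float(np.sqrt(1 - m2_obs)), p=p,
                      mode="COMP", n_perm=n_perm, n_items=len(samples))


def _pair_substitution_counts(aligned: dict):
    """Pairwise comparable-site, transition and transversion counts."""
    ids = list(aligned)
    arr = np.frombuffer("".join(aligned[i] for i in ids).encode(), dtype="S1")
    arr = arr.reshape(len(ids), -1)
    gap = arr == b"-"
    purine = (arr == b"A") | (arr == b"G")
    n = len(ids)
    n_mat = np.zeros((n, n), dtype=int)
    ts = np.zeros((n, n), dtype=int)
    tv = np.zeros((n, n), dtype=int)
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1:]
        diff = (arr[i] != arr[i + 1:]) & ok
        same_class = purine[i] == purine[i + 1:]
        t = (diff & same_class).sum(axis=1)
        v = (diff & ~same_class).sum(axis=1)
        c = ok.sum(axis=1)
        n_mat[i, i + 1:] = n_mat[i + 1:, i] = c
        ts[i, i + 1:] = ts[i + 1:, i] = t
        tv[i, i + 1:] = tv[i + 1:, i] = v
    return ids, n_mat, ts, tv


def _jc_matrix(n_mat, ts, tv):
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_mat > 0, (ts + tv) / np.maximum(n_mat, 1), np.nan)
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 / 3.0 * np.minimum(p, 0.7499)), np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def _k80_matrix(n_mat, ts, tv):
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / np.maximum(n_mat, 1)
        Q = tv / np.maximum(n_mat, 1)
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        d = np.where((a > 0) & (b > 0),
                     -0.5 * np.log(np.maximum(a, 1e-300))
                     - 0.25 * np.log(np.maximum(b, 1e-300)),
                     np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def _raw_matrix(n_mat, ts, tv):
    with np.errstate(invalid="ignore"):
        d = (ts + tv) / np.maximum(n_mat, 1)
    np.fill_diagonal(d, 0.0)
    return d


def _aicc(lnl: float, k: int, n_obs: int) -> float:
    pen = 2.0 * k
    if n_obs > k + 1:
        pen += 2.0 * k * (k + 1) / (n_obs - k - 1)
    return pen - 2.0 * lnl


def genetic_distances(aligned: dict, model: str = "auto"):
    """Pairwise genetic distances among a BTU's aligned ASVs.

    model "JC69", "K80" or "raw" applies that correction directly;
    "auto" chooses between JC69 and K80 by AICc of the summed two-sequence
    likelihoods (ties favor the simpler JC69).  If the chosen correction
    saturates any pair (+inf), the BTU falls back to raw mismatch fractions
    and the returned model tag is "raw".

    Returns (DistanceMatrix, model_used).
    """
    if len(aligned) < 3:
        raise UntestableError("genetic distances need >= 3 ASVs")
    ids, n_mat, ts, tv = _pair_substitution_counts(aligned)
    iu = np.triu_indices(len(ids), 1)
    if (n_mat[iu] == 0).any():
        raise UntestableError("some ASV pair shares no comparable sites")

    if model == "auto":
        # two-sequence likelihoods summed over pairs, with per-pair
        # parameters (one distance for JC69; distance + transition bias for
        # K80), mirroring how the distances themselves are estimated
        nn, t, v = n_mat[iu].astype(float), ts[iu].astype(float), tv[iu].astype(float)
        match = nn - t - v
        p = (t + v) / nn
        lnl_jc = float((xlogy(match, 1 - p) + xlogy(t + v, p / 3)).sum())
        P, Q = t / nn, v / nn
        lnl_k80 = float((xlogy(match, np.maximum(1 - P - Q, 1e-300))
                         + xlogy(t, P) + xlogy(v, np.maximum(Q / 2, 1e-300))).sum())
        n_pairs = len(nn)
        n_obs = int(nn.sum())
        model = "JC69" if _aicc(lnl_jc, n_pairs, n_obs) <= _aicc(
            lnl_k80, 2 * n_pairs, n_obs) else "K80"

    if model == "JC69":
        d = _jc_matrix(n_mat, ts, tv)
    elif model == "K80":
        d = _k80_matrix(n_mat, ts, tv)
    elif model == "raw":
        d = _raw_matrix(n_mat, ts, tv)
    else:
        raise ValueError(f"unknown substitution model {model!r}")

    if model != "raw" and np.isinf(d[iu]).any():
        logger.warning("saturated %s distances; falling back to raw p-distances", model)
        d = _raw_matrix(n_mat, ts, tv)
        model = "raw"
    return DistanceMatrix(d, ids), model


def paco_phylogenetic(asv_dist: DistanceMatrix, host_coph: DistanceMatrix,
                      incidence, species_of_sample: pd.Series,
                      n_perm: int = 10000, seed: int = 0, btu: str = "",
                      exact_perm: bool = False) -> PacoResult:
    """Phylogenetic co-divergence: ASV genetic vs host distances via occurrences.

    ``incidence`` is a list of (asv_id, sample_id) pairs with count >= 1; the
    explanatory matrix takes the host-side PCoA row of each occurrence's
    sample and the response takes the ASV-side PCoA row of its ASV.
    """
    incidence = list(incidence)
    if len(incidence) < 3:
        raise UntestableError("P_PHYLO needs >= 3 occurrence pairs")
    samples = sorted({s for _, s in incidence})
    spp = species_of_sample.loc[samples]
    if spp.nunique() < 2:
        raise UntestableError("P_PHYLO needs >= 2 host species")

    x = pcoa(sample_level_host_distances(host_coph, spp))
    y = pcoa(asv_dist)
    sample_pos = {s: i for i, s in enumerate(x.ids)}
    asv_pos = {a: i for i, a in enumerate(y.ids)}
    occ_samples = np.array([sample_pos[s] for _, s in incidence])
    occ_asvs = np.array([asv_pos[a] for a, _ in incidence])
    y_stack = y.coords[occ_asvs]
    m2_obs = procrustes_m2(x.coords[occ_samples], y_stack)

    rng = np.random.default_rng(seed)
    m2_perm = np.empty(n_perm)
    if exact_perm:
        for i in range(n_perm):
            permuted = pd.Series(block_permute(spp.values, rng), index=spp.index)
            xp = pcoa(sample_level_host_distances(host_coph, permuted))
            pos = {s: k for k, s in enumerate(xp.ids)}
            rows = np.array([pos[s] for _, s in incidence])
            m2_perm[i] = procrustes_m2(xp.coords[rows], y_stack)
    else:
        uniq, reps, codes = _species_representative_coords(x, spp)
        occ_codes = codes[occ_samples]
        for i in range(n_perm):
            perm = rng.permutation(len(uniq))
            m2_perm[i] = procrustes_m2(reps[perm][occ_codes], y_stack)

    p = _paco_p(m2_obs, m2_perm, n_perm)
    return PacoResult(btu=btu, m2=m2_obs, r=float(np.sqrt(1 - m2_obs)), p=p,
                      mode="PHYLO", n_perm=n_perm, n_items=len(incidence))


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
           seed: int = 0) -> tuple:
    """Mantel correlation of two distance matrices over matching items.

    Pearson r of the off-diagonal upper triangles; one-sided p from jointly
    permuting rows+columns of the first matrix.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("Mantel requires matching item sets")
    n = len(d1.ids)
    if n < 4:
        raise UntestableError("Mantel needs >= 4 items")
    order = [list(d2.ids).index(i) for i in d1.ids]
    m1 = d1.data
    m2m = d2.data[np.ix_(order, order)]
    iu = np.triu_indices(n, 1)

    def corr(a, b):
        av, bv = a[iu], b[iu]
        av = av - av.mean()
        bv = bv - bv.mean()
        den = np.sqrt((av**2).sum() * (bv**2).sum())
        if den == 0:
            raise UntestableError("constant distance matrix in Mantel test")
        return float((av * bv).sum() / den)

    r_obs = corr(m1, m2m)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr(m1[np.ix_(idx, idx)], m2m) >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)
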