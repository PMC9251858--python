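"""Decomposition of an ASV set into Binned Taxonomic Units (BTUs).

Two routes are provided.  The reference-based route groups ASVs by their
genus-level taxonomic assignment (ASVs without a genus are excluded).  The
reference-free route aligns the 16S marker sequences, computes pairwise
Jukes-Cantor-corrected distances, and cuts a complete-linkage dendrogram at
``1 - similarity``, which guarantees that every pair of ASVs inside a BTU is
at most that far apart.

The similarity threshold is applied on the corrected-distance scale by
default (cut heights 0.03 / 0.05 for 97% / 95% similarity); pass
``correction="raw"`` to `pairwise_distances` to cut on uncorrected mismatch
fractions instead, since corrected distance is not exactly 1 - identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .errors import UndefinedDistanceError
from .profiles_io import UNASSIGNED

logger = logging.getLogger(__name__)

#: sentinel replacement for +inf distances inside the linkage step
_NEVER_MERGE = 1.0e9

#: distances at/above this mismatch fraction are JC-saturated
SATURATION_P = 0.75


@dataclass
class BTUPartition:
    """A disjoint assignment of ASVs to BTU labels.

    ``method`` tags the provenance: ``genus`` (reference-based) or
    ``sim95``/``sim97`` (reference-free at that similarity threshold).
    """

    method: str
    btus: dict = field(default_factory=dict)  # label -> tuple of ASV IDs
    n_excluded: int = 0  # ASVs not binned (e.g. genus unassigned)

    def __post_init__(self):
        seen = set()
        for label, asvs in self.btus.items():
            for a in asvs:
                if a in seen:
                    raise ValueError(f"ASV {a} assigned to multiple BTUs")
                seen.add(a)

    @property
    def n_btus(self) -> int:
        return len(self.btus)

    @property
    def asv_to_btu(self) -> dict:
        return {a: label for label, asvs in self.btus.items() for a in asvs}

    def covered_asvs(self) -> set:
        return {a for asvs in self.btus.values() for a in asvs}

    def summary(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Per-BTU read totals and ASV counts against a count table."""
        rows = []
        for label in sorted(self.btus):
            asvs = [a for a in self.btus[label] if a in counts.columns]
            rows.append({
                "btu": label,
                "n_asvs": len(self.btus[label]),
                "reads": int(counts[asvs].values.sum()) if asvs else 0,
            })
        return pd.DataFrame(rows, columns=["btu", "n_asvs", "reads"]).set_index("btu")


def bin_by_genus(taxonomy: pd.DataFrame) -> BTUPartition:
    """One BTU per distinct genus string; unassigned ASVs are excluded."""
    genus = taxonomy["genus"].fillna(UNASSIGNED)
    assigned = genus[genus.str.lower() != UNASSIGNED]
    n_excluded = len(genus) - len(assigned)
    if n_excluded == len(genus):
        logger.warning("no ASV has a genus assignment; empty partition")
    btus = {g: tuple(sorted(idx)) for g, idx in assigned.groupby(assigned).groups.items()}
    logger.info("genus binning: %d BTUs, %d/%d ASVs excluded",
                len(btus), n_excluded, len(genus))
    return BTUPartition(method="genus", btus=btus, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# center-star multiple alignment


def _kmer_profiles(seqs: list, k: int = 4) -> np.ndarray:
    base = {c: i for i, c in enumerate("ACGT")}
    n_kmers = 4**k
    out = np.zeros((len(seqs), n_kmers), dtype=np.int32)
    mult = 4 ** np.arange(k)[::-1]
    for row, s in enumerate(seqs):
        codes = np.array([base.get(c, 0) for c in s])
        if len(codes) < k:
            continue
        idx = np.lib.stride_tricks.sliding_window_view(codes, k) @ mult
        np.add.at(out[row], idx, 1)
    return out


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def align_sequences(seqs: dict) -> dict:
    """Center-star multiple alignment of ungapped nucleotide sequences.

    Equal-length inputs are returned unchanged: for same-locus amplicons the
    indel-free assumption makes coordinate positions homologous, and running
    a scoring aligner across deeply divergent (saturated) sequence groups
    would instead chase chance matches and distort within-group distances.
    When lengths differ, the center is the sequence minimizing summed k-mer
    (city-block) distance to all others; every other sequence is globally
    aligned to it (match +1, mismatch -1, gap -2) and the pairwise gap
    patterns are merged.
    """
    if not seqs:
        raise ValueError("align_sequences requires at least one sequence")
    ids = list(seqs)
    if len(ids) == 1 or len({len(s) for s in seqs.values()}) == 1:
        return dict(seqs)

    strings = [seqs[i] for i in ids]
    profiles = _kmer_profiles(strings)
    # summed city-block distance to all others, chunked to bound memory
    totals = np.zeros(len(ids))
    for start in range(0, len(ids), 256):
        block = profiles[start:start + 256]
        d = np.abs(block[:, None, :] - profiles[None, :, :]).sum(axis=2)
        totals[start:start + 256] = d.sum(axis=1)
    center_idx = int(np.argmin(totals))
    center = strings[center_idx]

    aligner = _global_aligner()
    pairwise = {}  # id -> (center_aligned, seq_aligned)
    for i, sid in enumerate(ids):
        if i == center_idx:
            continue
        aln = aligner.align(center, strings[i])[0]
        ca, sa = str(aln[0]), str(aln[1])
        pairwise[sid] = (ca, sa)

    # merged gap pattern: max insertions between consecutive center positions
    L = len(center)
    ins = np.zeros(L + 1, dtype=int)
    for ca, _ in pairwise.values():
        pos = 0
        run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[L] = max(ins[L], run)

    def expand(ca: str, sa: str) -> str:
        """Re-gap one pairwise alignment onto the merged center pattern."""
        out = []
        pos = 0
        run = []
        for c_ch, s_ch in zip(ca, sa):
            if c_ch == "-":
                run.append(s_ch)
            else:
                out.append("".join(run) + "-" * (ins[pos] - len(run)))
                out.append(s_ch)
                run = []
                pos += 1
        out.append("".join(run) + "-" * (ins[L] - len(run)))
        return "".join(out)

    aligned = {}
    center_gapped = expand(center, center)
    for i, sid in enumerate(ids):
        if i == center_idx:
            aligned[sid] = center_gapped
        else:
            aligned[sid] = expand(*pairwise[sid])
    lengths = {len(s) for s in aligned.values()}
    assert len(lengths) == 1, "center-star merge produced ragged alignment"
    return {sid: aligned[sid] for sid in ids}


# ---------------------------------------------------------------------------
# distances


def jc_distance(aligned_i: str, aligned_j: str) -> float:
    """Jukes-Cantor-corrected distance between two gapped sequences.

    Sites where either sequence has a gap are ignored.  Mismatch fractions at
    or beyond 3/4 are saturated and return +inf.
    """
    if len(aligned_i) != len(aligned_j):
        raise ValueError("aligned sequences must have equal gapped length")
    a = np.frombuffer(aligned_i.encode(), dtype="S1")
    b = np.frombuffer(aligned_j.encode(), dtype="S1")
    ok = (a != b"-") & (b != b"-")
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable (gap-free) sites")
    p = float((a[ok] != b[ok]).sum()) / n
    return p_to_jc(p)


def p_to_jc(p: float) -> float:
    """Closed-form JC69 correction; saturates to +inf at p >= 3/4."""
    if p < 0:
        raise ValueError("mismatch fraction must be >= 0")
    if p >= SATURATION_P:
        return np.inf
    return -0.75 * np.log1p(-4.0 / 3.0 * p)


def _encode(aligned: dict):
    ids = list(aligned)
    arr = np.frombuffer("".join(aligned[i] for i in ids).encode(), dtype="S1")
    arr = arr.reshape(len(ids), -1)
    return ids, arr


def mismatch_fractions(aligned: dict):
    """All pairwise (p, n_comparable) over gap-free site pairs, vectorized.

    Returns (ids, p_matrix, n_matrix).
    """
    ids, arr = _encode(aligned)
    n = len(ids)
    gap = arr == b"-"
    p_mat = np.zeros((n, n))
    n_mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1:]
        cnt = ok.sum(axis=1)
        mism = ((arr[i] != arr[i + 1:]) & ok).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(cnt > 0, mism / np.maximum(cnt, 1), np.nan)
        p_mat[i, i + 1:] = p
        p_mat[i + 1:, i] = p
        n_mat[i, i + 1:] = cnt
        n_mat[i + 1:, i] = cnt
    return ids, p_mat, n_mat


def pairwise_distances(aligned: dict, correction: str = "jc") -> DistanceMatrix:
    """Pairwise distance matrix over an alignment.

    correction="jc" applies the Jukes-Cantor transform (saturated pairs get
    +inf); correction="raw" returns plain mismatch fractions.
    """
    ids, p_mat, n_mat = mismatch_fractions(aligned)
    if np.isnan(p_mat[np.triu_indices(len(ids), 1)]).any():
        raise UndefinedDistanceError("some ASV pair shares no gap-free sites")
    if correction == "jc":
        d = np.where(p_mat >= SATURATION_P, np.inf,
                     -0.75 * np.log1p(-4.0 / 3.0 * np.minimum(p_mat, SATURATION_P - 1e-12)))
        np.fill_diagonal(d, 0.0)
    elif correction == "raw":
        d = p_mat
    else:
        raise ValueError("correction must be 'jc' or 'raw'")
    return DistanceMatrix(d, ids)


def complete_linkage_bins(dist: DistanceMatrix, similarity_threshold: float) -> BTUPartition:
    """Cut a complete-linkage dendrogram at height 1 - similarity.

    Guarantees max within-BTU pairwise distance <= cut height.  +inf
    distances never merge.  Singleton BTUs are kept (downstream filters
    remove them).
    """
    if not 0 < similarity_threshold < 1:
        raise ValueError("similarity_threshold must be in (0, 1)")
    h = 1.0 - similarity_threshold
    ids = list(dist.ids)
    if len(ids) == 1:
        method = f"sim{int(round(similarity_threshold * 100))}"
        return BTUPartition(method=method, btus={f"{method}_BTU0001": tuple(ids)})
    mat = dist.data.copy()
    mat[np.isinf(mat)] = _NEVER_MERGE
    condensed = squareform(mat, checks=False)
    Z = linkage(condensed, method="complete")
    flat = fcluster(Z, t=h, criterion="distance")
    # relabel clusters by first-ASV appearance for determinism
    order = {}
    for asv, c in zip(ids, flat):
        order.setdefault(c, len(order) + 1)
    method = f"sim{int(round(similarity_threshold * 100))}"
    btus: dict = {}
    for asv, c in zip(ids, flat):
        label = f"{method}_BTU{order[c]:04d}"
        btus.setdefault(label, []).append(asv)
    btus = {k: tuple(v) for k, v in btus.items()}
    part = BTUPartition(method=method, btus=btus)
    assert_within_btu_guarantee(part, dist, h)
    return part


def assert_within_btu_guarantee(partition: BTUPartition, dist: DistanceMatrix,
                                cut_height: float) -> None:
    """Post-hoc check of the complete-linkage similarity floor."""
    idx = {a: i for i, a in enumerate(dist.ids)}
    for label, asvs in partition.btus.items():
        if len(asvs) < 2:
            continue
        pos = [idx[a] for a in asvs]
        sub = dist.data[np.ix_(pos, pos)]
        worst = sub.max()
        if worst > cut_height + 1e-12:
            raise AssertionError(
                f"BTU {label} violates complete-linkage guarantee: "
                f"max within distance {worst} > {cut_height}")


def filter_btus(partition: BTUPartition, counts: pd.DataFrame,
                min_reads: int = 5000, min_asvs: int = 10) -> BTUPartition:
    """Keep BTUs with at least ``min_reads`` reads and ``min_asvs`` ASVs.

    Both thresholds are inclusive.  The retained read fraction is logged.
    """
    total = counts.values.sum()
    keep = {}
    kept_reads = 0
    for label, asvs in partition.btus.items():
        present = [a for a in asvs if a in counts.columns]
        reads = int(counts[present].values.sum()) if present else 0
        if len(asvs) >= min_asvs and reads >= min_reads:
            keep[label] = asvs
            kept_reads += reads
    frac = kept_reads / total if total else 0.0
    logger.info("BTU filter (%s): kept %d/%d BTUs, %.1f%% of reads",
                partition.method, len(keep), partition.n_btus, 100 * frac)
    return BTUPartition(method=partition.method, btus=keep,
                        n_excluded=partition.n_excluded)
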