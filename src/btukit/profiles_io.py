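"""Loading, validation and filtering of microbiota profile datasets.

A dataset bundles five artifacts: an ASV count table (samples x ASVs), the ASV
marker sequences, an ASV taxonomy table (phylum..genus), per-sample host
species metadata, and a host phylogeny.  Loaders keep IDs verbatim and
cross-validate that the count table, FASTA and taxonomy describe the same ASV
set and that every sample's host species is a tip of the tree.

Filtering follows the upstream conventions of 16S amplicon studies: ASVs
without a phylum-level assignment or assigned to Chloroplasts, Mitochondria or
Archaea are dropped first, and only then are low-coverage samples (library
size below a read threshold) removed, so that library sizes reflect the
retained bacterial ASVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

from .errors import EmptyDatasetError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Taxonomic ranks carried by the taxonomy table, coarsest first.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Rank values triggering removal (case-insensitive prefix match).
REMOVE_TAXA = ("chloroplast", "mitochondria", "archaea")

#: String used for an unassigned rank in taxonomy TSVs.
UNASSIGNED = "unassigned"


@dataclass
class Dataset:
    """In-memory view of the five cross-referenced input artifacts.

    Attributes
    ----------
    counts : pd.DataFrame
        Integer read counts, rows = samples, columns = ASVs.
    sequences : dict[str, str]
        ASV ID -> ungapped nucleotide sequence.
    taxonomy : pd.DataFrame
        Indexed by ASV ID, columns ``RANKS``; unassigned ranks hold
        ``"unassigned"``.
    metadata : pd.Series
        Sample ID -> host species label.
    tree : dendropy.Tree
        Rooted host phylogeny with species-labeled tips.
    """

    counts: pd.DataFrame
    sequences: dict
    taxonomy: pd.DataFrame
    metadata: pd.Series
    tree: dendropy.Tree

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    @property
    def species(self) -> list:
        return sorted(set(self.metadata))

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def summary(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "n_species": len(self.species),
            "n_asvs": int(self.n_asvs),
            "total_reads": int(self.counts.values.sum()),
        }


def _tip_labels(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def validate_dataset(ds: Dataset) -> None:
    """Raise ValidationError on any cross-reference inconsistency."""
    asvs = list(ds.counts.columns)
    if len(set(asvs)) != len(asvs):
        raise ValidationError("duplicate ASV IDs in count table")
    samples = list(ds.counts.index)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample IDs in count table")
    if (ds.counts.values < 0).any():
        raise ValidationError("negative counts in abundance table")

    fasta_ids = set(ds.sequences)
    missing = sorted(set(asvs) - fasta_ids)
    if missing:
        raise ValidationError(f"ASVs missing from FASTA: {missing[:10]}")
    tax_missing = sorted(set(asvs) - set(ds.taxonomy.index))
    if tax_missing:
        raise ValidationError(f"ASVs missing from taxonomy: {tax_missing[:10]}")

    meta_missing = sorted(set(samples) - set(ds.metadata.index))
    if meta_missing:
        raise ValidationError(f"samples missing from metadata: {meta_missing[:10]}")
    tips = set(_tip_labels(ds.tree))
    bad_species = sorted(set(ds.metadata.loc[samples]) - tips)
    if bad_species:
        raise ValidationError(f"species not in host tree: {bad_species[:10]}")


def load_dataset(counts_path, fasta_path, taxonomy_path, metadata_path, tree_path) -> Dataset:
    """Load and cross-validate the five input files.

    Counts, taxonomy and metadata are TSV; sequences FASTA; tree Newick.
    """
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - normalize to ParseError
        raise ParseError(f"cannot parse counts TSV {counts_path}: {exc}") from exc
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ParseError(f"counts table {counts_path} is empty")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts = counts.astype(np.int64)

    try:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    if not sequences:
        raise ParseError(f"FASTA {fasta_path} contains no sequences")

    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    taxonomy.index = taxonomy.index.astype(str)
    missing_ranks = [r for r in RANKS if r not in taxonomy.columns]
    if missing_ranks:
        raise ParseError(f"taxonomy table lacks ranks {missing_ranks}")
    taxonomy = taxonomy[list(RANKS)].fillna(UNASSIGNED)

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    if meta.shape[1] < 1:
        raise ParseError("metadata table needs a species column")
    metadata = meta.iloc[:, 0]
    metadata.index = metadata.index.astype(str)

    try:
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse Newick {tree_path}: {exc}") from exc

    ds = Dataset(counts=counts, sequences=sequences, taxonomy=taxonomy,
                 metadata=metadata, tree=tree)
    validate_dataset(ds)
    logger.info("loaded dataset: %s", ds.summary())
    return ds


def write_dataset(ds: Dataset, outdir) -> None:
    """Write the five artifacts as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="sample")
    records = [SeqRecord(Seq(seq), id=asv, description="") for asv, seq in ds.sequences.items()]
    SeqIO.write(records, str(outdir / "sequences.fasta"), "fasta")
    ds.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index_label="asv")
    ds.metadata.rename("species").to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample")
    ds.tree.write(path=str(outdir / "host_tree.nwk"), schema="newick")


def _subset_asvs(ds: Dataset, keep) -> Dataset:
    keep = [a for a in ds.counts.columns if a in set(keep)]
    return replace(
        ds,
        counts=ds.counts[keep],
        sequences={a: ds.sequences[a] for a in keep},
        taxonomy=ds.taxonomy.loc[keep],
    )


def filter_taxa(ds: Dataset) -> Dataset:
    """Drop ASVs with unassigned phylum or any rank matching an excluded taxon.

    Matching is a case-insensitive prefix match against Chloroplast,
    Mitochondria and Archaea (database spellings vary).
    """
    tax = ds.taxonomy
    unassigned_phylum = tax["phylum"].str.lower().eq(UNASSIGNED) | tax["phylum"].eq("")
    excluded = pd.Series(False, index=tax.index)
    for rank in RANKS:
        low = tax[rank].str.lower()
        for bad in REMOVE_TAXA:
            excluded |= low.str.startswith(bad)
    drop = unassigned_phylum | excluded
    logger.info("taxon filter: removing %d of %d ASVs", int(drop.sum()), len(tax))
    return _subset_asvs(ds, tax.index[~drop])


def filter_samples(ds: Dataset, min_reads: int = 1000) -> Dataset:
    """Remove samples whose library size is strictly below ``min_reads``.

    Library sizes are computed on the current (taxon-filtered) table.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    lib = ds.library_sizes()
    keep = lib.index[lib >= min_reads]
    if len(keep) == 0:
        raise EmptyDatasetError(f"no sample has >= {min_reads} reads")
    logger.info("sample filter: keeping %d of %d samples", len(keep), ds.n_samples)
    return replace(
        ds,
        counts=ds.counts.loc[keep],
        metadata=ds.metadata.loc[keep],
    )


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix of a phylogeny."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace if tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, labels)
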