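"""Synthetic host trees and ASV communities with planted specificity regimes.

The generator emulates the *shape* of a processed cross-species 16S amplicon
survey (many host species, a handful of fecal samples per species, thousands
of ASVs, libraries of a few thousand reads) while planting per-BTU ground
truth so every downstream stage is testable without any sequencing data:

``null``
    every ASV has the same expected relative abundance in every host species;
``specific``
    each ASV's affinity vector over host species is Dirichlet(alpha)
    distributed (small alpha concentrates an ASV on few, phylogenetically
    random species), so composition depends on species identity but not on
    host phylogeny;
``codiverging``
    the BTU carries one ASV per host species, its guide tree mirrors the host
    tree, and ASV i's affinity for species j decays with host cophenetic
    distance, exp(-d(i,j)/(tau*H)) blended with a uniform floor (the leakage
    strength knob), so both composition and ASV genetic divergence track the
    host phylogeny continuously.

Sequences evolve indel-free under JC69 along per-BTU guide trees from
independent uniform-random roots, so different BTUs are saturated apart while
within-BTU divergence is controlled by ``substitution_rate``.  Counts are
multinomial draws from species-specific expected compositions with negative
binomial library sizes.

One RNG stream per dataset is split hierarchically by stable keys, in this
order: host tree; per BTU (guide tree, sequences, affinities, base
abundances); library sizes; per-sample counts.  Same seed, same output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._rng import child_rng
from .profiles_io import RANKS, Dataset, cophenetic_distances, write_dataset

REGIMES = ("null", "specific", "codiverging")

_NT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-shape and effect-strength knobs for one synthetic dataset.

    Defaults give the desk-scale configuration used throughout the test
    suite: 20 host species x 5 samples, 12 BTUs (4 per regime) x 25 ASVs,
    250 nt markers, mean library 6000 reads.
    """

    n_species: int = 20
    samples_per_species: int | tuple = 5
    n_btus_per_regime: dict = field(
        default_factory=lambda: {"null": 4, "specific": 4, "codiverging": 4})
    asvs_per_btu: int = 25
    seq_length: int = 250
    #: expected substitutions/site from root to tip of a (unit-height) guide tree
    substitution_rate: float = 0.005
    #: Dirichlet concentration for 'specific' BTUs; smaller = stronger specificity
    specificity_concentration: float = 0.1
    #: uniform affinity floor for 'codiverging' BTUs; 0 = perfect co-divergence
    codivergence_leakage: float = 0.0
    #: e-folding scale of the phylogenetic affinity kernel, in tree heights
    phylo_kernel_scale: float = 0.2
    mean_library_size: float = 6000.0
    #: negative binomial size parameter; larger = tighter library sizes
    library_dispersion: float = 10.0
    #: sigma of the per-ASV lognormal base-abundance profile (0 = even ASVs)
    abundance_lognormal_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50")
        if self.specificity_concentration <= 0:
            raise ValueError("specificity_concentration must be > 0")
        if not 0 <= self.codivergence_leakage <= 1:
            raise ValueError("codivergence_leakage must be in [0, 1]")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if self.asvs_per_btu < 1 or self.mean_library_size < 1:
            raise ValueError("counts must be >= 1")
        spp = self.samples_per_species
        if isinstance(spp, int):
            if spp < 1:
                raise ValueError("samples_per_species must be >= 1")
        else:
            spp = tuple(int(x) for x in spp)
            if len(spp) != self.n_species or min(spp) < 1:
                raise ValueError("per-species sample vector must have n_species entries >= 1")
            object.__setattr__(self, "samples_per_species", spp)
        for regime in self.n_btus_per_regime:
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}")

    def samples_vector(self) -> np.ndarray:
        if isinstance(self.samples_per_species, int):
            return np.full(self.n_species, self.samples_per_species, dtype=int)
        return np.asarray(self.samples_per_species, dtype=int)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-BTU regime/strength and ASV affinities."""

    species: list
    btu_regime: dict
    btu_strength: dict
    #: (btu, asv) -> affinity probability vector over ``species`` (sums to 1)
    species_affinity: dict
    asv_to_btu: dict

    def btus(self, regime=None) -> list:
        if regime is None:
            return sorted(self.btu_regime)
        return sorted(b for b, r in self.btu_regime.items() if r == regime)


def _yule_newick(labels, rng) -> str:
    """Newick of an ultrametric pure-birth tree over ``labels`` (rate 1)."""
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 tips")
    # forward simulation: each active lineage splits at rate 1
    next_id = 0
    root = {"id": next_id, "birth": 0.0, "children": None, "split": None}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node["split"] = t
        kids = []
        for _ in range(2):
            next_id += 1
            kids.append({"id": next_id, "birth": t, "children": None, "split": None})
        node["children"] = kids
        active.extend(kids)
    present = t + rng.exponential(1.0 / n)

    leaves = []

    def collect(node):
        if node["children"] is None:
            leaves.append(node)
        else:
            for k in node["children"]:
                collect(k)

    collect(root)
    order = rng.permutation(n)
    for leaf, pos in zip(leaves, order):
        leaf["label"] = labels[pos]

    def render(node) -> str:
        if node["children"] is None:
            return f"{node['label']}:{present - node['birth']:.10f}"
        inner = ",".join(render(k) for k in node["children"])
        return f"({inner}):{node['split'] - node['birth']:.10f}"

    # the tree starts at the first split: no root edge, so the deepest
    # tip pair is separated by exactly twice the tree height
    inner = ",".join(render(k) for k in root["children"])
    return f"({inner});"


def _as_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def rescale_tree(tree: dendropy.Tree, height: float = 1.0) -> dendropy.Tree:
    """Rescale all branch lengths so the deepest tip sits at ``height``."""
    h = tree_height(tree)
    if h > 0:
        factor = height / h
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return tree


def simulate_host_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) host phylogeny with labeled tips."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    rng = np.random.default_rng(seed)
    return _as_tree(_yule_newick(labels, rng))


def simulate_btu_sequences(root_length: int, n_asvs: int, guide_tree: dendropy.Tree,
                           substitution_rate: float, seed: int) -> dict:
    """Evolve one sequence per guide-tree tip under JC69 from a random root.

    Site-independent, indel-free.  A branch of length ``b`` substitutes each
    site with probability (3/4)(1 - exp(-(4/3) * rate * b)), uniformly to one
    of the three other bases.
    """
    if substitution_rate < 0:
        raise ValueError("substitution_rate must be >= 0")
    tips = [lf.taxon.label for lf in guide_tree.leaf_node_iter()]
    if len(tips) != n_asvs:
        raise ValueError(f"guide tree has {len(tips)} tips, expected {n_asvs}")
    rng = np.random.default_rng(seed)
    root_state = rng.integers(0, 4, size=root_length)

    out = {}
    stack = [(guide_tree.seed_node, root_state)]
    while stack:
        node, state = stack.pop()
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * substitution_rate * b))
            hits = rng.random(root_length) < p_change
            new_state = state.copy()
            if hits.any():
                # uniform over the three other bases
                shift = rng.integers(1, 4, size=int(hits.sum()))
                new_state[hits] = (new_state[hits] + shift) % 4
            if child.is_leaf():
                out[child.taxon.label] = "".join(_NT[new_state])
            else:
                stack.append((child, new_state))
    return out


def _mirrored_guide_tree(host_tree: dendropy.Tree, tip_map: dict) -> dendropy.Tree:
    """Clone the host tree and relabel its tips through ``tip_map``."""
    clone = _as_tree(host_tree.as_string(schema="newick"))
    for lf in clone.leaf_node_iter():
        lf.taxon.label = tip_map[lf.taxon.label]
    return clone


def _btu_plan(config: SimulationConfig) -> list:
    plan = []
    idx = 0
    for regime in REGIMES:
        for _ in range(int(config.n_btus_per_regime.get(regime, 0))):
            plan.append((f"BTU{idx:03d}", regime))
            idx += 1
    if not plan:
        raise ValueError("no BTUs configured")
    return plan


def simulate_dataset(config: SimulationConfig):
    """Generate a full synthetic dataset and its planted truth.

    Returns
    -------
    (Dataset, SyntheticTruth)
        The dataset bundles counts, sequences, taxonomy, metadata and the
        host tree; the truth records regimes, strengths and affinities.
    """
    seed = config.seed
    host_tree = simulate_host_tree(config.n_species, child_rng(seed, "host_tree").integers(2**31))
    rescale_tree(host_tree, 1.0)
    species = sorted(lf.taxon.label for lf in host_tree.leaf_node_iter())
    coph = cophenetic_distances(host_tree)
    coph_arr = np.array([[coph[si, sj] for sj in species] for si in species])
    height = tree_height(host_tree)
    S = config.n_species

    plan = _btu_plan(config)
    sequences: dict = {}
    regime_of: dict = {}
    strength_of: dict = {}
    affinity: dict = {}
    asv_to_btu: dict = {}
    tax_rows = []
    # per-ASV expected within-BTU share for each species, filled below
    asv_ids_all: list = []
    weight_blocks = []

    asv_counter = 0
    for b_idx, (btu, regime) in enumerate(plan):
        regime_of[btu] = regime
        if regime == "codiverging":
            n_asvs = S
        else:
            n_asvs = config.asvs_per_btu
        asv_ids = [f"ASV{asv_counter + i:05d}" for i in range(n_asvs)]
        asv_counter += n_asvs

        guide_rng = child_rng(seed, "guide", btu)
        if regime == "codiverging":
            tip_map = {sp: asv for sp, asv in zip(species, asv_ids)}
            guide = _mirrored_guide_tree(host_tree, tip_map)
        else:
            guide = _as_tree(_yule_newick(asv_ids, guide_rng))
        rescale_tree(guide, 1.0)
        seqs = simulate_btu_sequences(
            config.seq_length, n_asvs, guide, config.substitution_rate,
            child_rng(seed, "seqs", btu).integers(2**31))
        sequences.update(seqs)

        aff_rng = child_rng(seed, "affinity", btu)
        aff = np.empty((n_asvs, S))
        if regime == "null":
            aff[:] = 1.0 / S
            strength_of[btu] = 0.0
        elif regime == "specific":
            alpha = config.specificity_concentration
            aff[:] = aff_rng.dirichlet(np.full(S, alpha), size=n_asvs)
            strength_of[btu] = alpha
        else:  # codiverging: phylogenetic decay kernel around the matched species
            eps = config.codivergence_leakage
            tau = config.phylo_kernel_scale * height
            kernel = np.exp(-coph_arr / tau)  # row i: affinity of ASV i across species
            kernel /= kernel.sum(axis=1, keepdims=True)
            aff[:] = (1.0 - eps) * kernel + eps / S
            strength_of[btu] = 1.0 - eps
        aff /= aff.sum(axis=1, keepdims=True)

        # per-ASV base abundances (shared across species, so the null regime
        # keeps identical expected composition in every species while ASV
        # occupancy varies, as in real communities)
        base = child_rng(seed, "base", btu).lognormal(
            0.0, config.abundance_lognormal_sigma, size=n_asvs)

        for i, asv in enumerate(asv_ids):
            affinity[(btu, asv)] = aff[i]
            asv_to_btu[asv] = btu
            tax_rows.append({
                "asv": asv,
                "phylum": f"Phylum{(b_idx % 4) + 1}",
                "class": f"Class{(b_idx % 6) + 1}",
                "order": f"Order{(b_idx % 8) + 1}",
                "family": f"Family{b_idx + 1}",
                "genus": f"Genus_{btu}",
            })
        asv_ids_all.extend(asv_ids)
        # within-BTU share per species: base abundance x affinity, normalized
        # over the BTU's ASVs for each species
        w = base[:, None] * aff
        col_tot = w.sum(axis=0, keepdims=True)
        weight_blocks.append(w / np.where(col_tot > 0, col_tot, 1.0))

    n_btus = len(plan)
    # species x ASV expected proportions; BTUs contribute equal expected mass
    expected = np.hstack([w.T / n_btus for w in weight_blocks])  # S x n_asv
    expected /= expected.sum(axis=1, keepdims=True)

    samples_vec = config.samples_vector()
    sample_ids = []
    sample_species_idx = []
    for s_idx, sp in enumerate(species):
        for j in range(samples_vec[s_idx]):
            sample_ids.append(f"{sp}_s{j + 1}")
            sample_species_idx.append(s_idx)
    n_samples = len(sample_ids)

    lib_rng = child_rng(seed, "libraries")
    disp = config.library_dispersion
    p_nb = disp / (disp + config.mean_library_size)
    libs = lib_rng.negative_binomial(disp, p_nb, size=n_samples)
    libs = np.maximum(libs, 1)

    count_rng = child_rng(seed, "counts")
    counts = np.empty((n_samples, len(asv_ids_all)), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = count_rng.multinomial(libs[i], expected[sample_species_idx[i]])

    counts_df = pd.DataFrame(counts, index=sample_ids, columns=asv_ids_all)
    taxonomy = pd.DataFrame(tax_rows).set_index("asv")[list(RANKS)]
    metadata = pd.Series([species[i] for i in sample_species_idx],
                         index=sample_ids, name="species")

    ds = Dataset(counts=counts_df, sequences=sequences, taxonomy=taxonomy,
                 metadata=metadata, tree=host_tree)
    truth = SyntheticTruth(species=species, btu_regime=regime_of,
                           btu_strength=strength_of, species_affinity=affinity,
                           asv_to_btu=asv_to_btu)
    return ds, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "species": truth.species,
        "btu_regime": truth.btu_regime,
        "btu_strength": truth.btu_strength,
        "asv_to_btu": truth.asv_to_btu,
        "species_affinity": {
            f"{btu}|{asv}": [float(x) for x in vec]
            for (btu, asv), vec in truth.species_affinity.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_synthetic(ds: Dataset, truth: SyntheticTruth, outdir) -> None:
    """Write dataset artifacts plus the truth JSON under ``outdir``."""
    outdir = Path(outdir)
    write_dataset(ds, outdir)
    write_truth(truth, outdir / "truth.json")
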