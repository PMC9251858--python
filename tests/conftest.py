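"""Shared fixtures: small synthetic datasets and a hand-built toy dataset."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import btukit as bk
from btukit.profiles_io import Dataset


@pytest.fixture(scope="session")
def desk_dataset():
    """Default desk-scale dataset (20 species x 5 samples, 12 planted BTUs)."""
    ds, truth = bk.simulate_dataset(bk.SimulationConfig(seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small dataset for fast end-to-end runs."""
    cfg = bk.SimulationConfig(
        n_species=8, samples_per_species=3,
        n_btus_per_regime={"null": 1, "specific": 1, "codiverging": 1},
        asvs_per_btu=12, seq_length=120, mean_library_size=2000, seed=7)
    ds, truth = bk.simulate_dataset(cfg)
    return ds, truth


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def handmade_dataset():
    """A 3-species, 6-sample, 6-ASV dataset built by hand.

    ASV layout: a1-a3 (genus GA, spread over all species), a4 (genus GB,
    confined to species sp1), a5 unassigned at phylum level, a6 assigned as
    Chloroplast at order level.
    """
    rng = np.random.default_rng(0)
    samples = ["sp1_a", "sp1_b", "sp2_a", "sp2_b", "sp3_a", "sp3_b"]
    asvs = ["a1", "a2", "a3", "a4", "a5", "a6"]
    counts = pd.DataFrame(
        [[500, 300, 200, 100, 10, 5],
         [400, 400, 250, 80, 0, 0],
         [450, 350, 220, 0, 20, 3],
         [500, 280, 260, 0, 0, 0],
         [420, 380, 240, 0, 15, 2],
         [480, 320, 210, 0, 0, 0]],
        index=samples, columns=asvs)
    sequences = {a: _seq(rng, 80) for a in asvs}
    taxonomy = pd.DataFrame({
        "phylum": ["P1", "P1", "P1", "P2", "unassigned", "P3"],
        "class": ["C1"] * 6,
        "order": ["O1", "O1", "O1", "O2", "O1", "Chloroplast"],
        "family": ["F1"] * 6,
        "genus": ["GA", "GA", "GA", "GB", "GC", "GD"],
    }, index=asvs)
    metadata = pd.Series(["sp1", "sp1", "sp2", "sp2", "sp3", "sp3"],
                         index=samples, name="species")
    tree = dendropy.Tree.get(data="((sp1:1.0,sp2:1.0):0.5,sp3:1.5);",
                             schema="newick")
    return Dataset(counts=counts, sequences=sequences, taxonomy=taxonomy,
                   metadata=metadata, tree=tree)
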