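"""PCoA, Procrustes, block permutation, PACo, genetic distances, Mantel."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import btukit as bk
from btukit.codivergence import (block_permute, genetic_distances, mantel,
                                 paco_compositional, paco_phylogenetic, pcoa,
                                 procrustes_m2, sample_level_host_distances)
from btukit.errors import UntestableError
from btukit.profiles_io import cophenetic_distances

#: a rooted tree with all pairwise tip distances distinct (no automorphisms),
#: so the only permutation reproducing perfect congruence is the identity
ASYMMETRIC_NEWICK = ("(((((a:1.1,b:2.3):0.5,c:3.9):0.4,d:5.2):0.3,e:6.9):0.2,"
                     "(f:1.7,g:9.4):0.6);")


class TestPCoA:
    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        cfg = pcoa(DistanceMatrix(d, list("abc")))
        assert cfg.coords.shape[1] == 1
        rec = squareform(pdist(cfg.coords))
        assert np.allclose(rec, d, atol=1e-9)

    def test_euclidean_exactness(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        cfg = pcoa(DistanceMatrix(d, [str(i) for i in range(7)]))
        assert np.allclose(squareform(pdist(cfg.coords)), d, atol=1e-8)

    def test_non_euclidean_negative_eigenvalue_detected(self):
        # star K4: hub at 1 from three tips mutually at 2 cannot embed
        d = np.array([[0, 1, 1, 1], [1, 0, 2, 2], [1, 2, 0, 2], [1, 2, 2, 0]],
                     dtype=float)
        cfg = pcoa(DistanceMatrix(d, list("abcd")))
        assert cfg.min_eigenvalue < -1e-8


class TestProcrustes:
    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 2))
        theta = np.deg2rad(37)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 5.0 * x @ rot + 3.0
        assert procrustes_m2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_disparity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=(9, 3))
            y = rng.normal(size=(9, 3))
            _, _, disparity = scipy_procrustes(x, y)
            assert procrustes_m2(x, y) == pytest.approx(disparity, abs=1e-10)

    def test_zero_padding_equivalence(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=(12, 5))
        padded = np.hstack([x, np.zeros((12, 3))])
        assert procrustes_m2(x, y) == pytest.approx(procrustes_m2(padded, y),
                                                    abs=1e-12)

    def test_independent_configs_land_in_null_band(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 2))
        y = rng.normal(size=(100, 2))
        m2_obs = procrustes_m2(x, y)
        null = np.array([procrustes_m2(x[rng.permutation(100)], y)
                         for _ in range(200)])
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= m2_obs <= hi


class TestBlockPermute:
    def test_singleton_blocks_reduce_to_label_permutation(self):
        rng = np.random.default_rng(0)
        labels = np.array(["a", "b", "c", "d"])
        out = block_permute(labels, rng)
        assert sorted(out) == sorted(labels)

    def test_blocks_move_intact(self):
        rng = np.random.default_rng(1)
        labels = np.array(["A", "A", "B"])
        out = block_permute(labels, rng)
        assert out[0] == out[1]          # block {s1, s2} stays together
        assert out[2] != out[0]          # s3 gets the other identity
        assert sorted(set(out)) == ["A", "B"]

    def test_block_sizes_preserved(self):
        rng = np.random.default_rng(2)
        labels = np.array(["A"] * 3 + ["B"] * 2 + ["C"] * 4)
        for _ in range(20):
            out = block_permute(labels, rng)
            assert sorted(np.unique(out, return_counts=True)[1].tolist()) == [2, 3, 4]

    def test_singleton_draws_are_uniform_permutations(self):
        """Chi-square over the 6 permutations of 3 singleton blocks."""
        rng = np.random.default_rng(3)
        labels = np.array(["a", "b", "c"])
        from collections import Counter
        counts = Counter(tuple(block_permute(labels, rng)) for _ in range(1200))
        assert len(counts) == 6
        from scipy.stats import chisquare
        assert chisquare(list(counts.values())).pvalue > 0.01


class TestPacoCompositional:
    def test_perfect_congruence(self):
        """GM distances equal to host distances, one sample per species."""
        tree = dendropy.Tree.get(data=ASYMMETRIC_NEWICK, schema="newick")
        coph = cophenetic_distances(tree)
        samples = [s + "_x" for s in coph.ids]
        spp = pd.Series(list(coph.ids), index=samples)
        gm = DistanceMatrix(coph.data, samples)
        res = paco_compositional(gm, coph, spp, n_perm=999, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)
        # p sits at the add-one floor except for rare identity draws among
        # the 999 uniform permutations of 7 species
        assert res.p <= 5 / 1000

    def test_fast_and_exact_null_agree_for_balanced_design(self):
        rng = np.random.default_rng(5)
        tree = bk.simulate_host_tree(5, seed=8)
        coph = cophenetic_distances(tree)
        samples = [f"{sp}_{i}" for sp in coph.ids for i in range(2)]
        spp = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)
        pts = rng.normal(size=(10, 3))
        gm = DistanceMatrix(squareform(pdist(pts)), samples)
        fast = paco_compositional(gm, coph, spp, n_perm=499, seed=3)
        exact = paco_compositional(gm, coph, spp, n_perm=499, seed=3,
                                   exact_perm=True)
        assert fast.m2 == pytest.approx(exact.m2)
        assert abs(fast.p - exact.p) < 0.15

    def test_single_species_untestable(self):
        tree = bk.simulate_host_tree(4, seed=0)
        coph = cophenetic_distances(tree)
        sp = coph.ids[0]
        samples = [f"{sp}_{i}" for i in range(3)]
        spp = pd.Series([sp] * 3, index=samples)
        gm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]), samples)
        with pytest.raises(UntestableError):
            paco_compositional(gm, coph, spp, n_perm=99, seed=0)


class TestGeneticDistances:
    def test_identical_sequences_zero_for_all_models(self):
        seqs = {f"a{i}": "ACGTACGTAC" for i in range(4)}
        for model in ("raw", "JC69", "K80"):
            dm, used = genetic_distances(seqs, model=model)
            assert np.allclose(dm.data, 0)
            assert used == model

    def test_transition_only_k80_exceeds_jc(self):
        # one A->G transition in 10 sites: p = 0.1, all transitions
        seqs = {"a": "ACGTACGTAC", "b": "GCGTACGTAC", "c": "ACGTACGTAC"}
        jc, _ = genetic_distances(seqs, model="JC69")
        k80, _ = genetic_distances(seqs, model="K80")
        assert k80["a", "b"] > jc["a", "b"]

    def test_auto_selection_recovers_jc_on_jc_data(self):
        """JC-generated alignments mostly select JC69.

        AIC-family criteria retain the richer model on a minority of null
        realizations by construction (P(chi2_1 > 2) ~ 0.16 per independent
        comparison), so recovery is high but not certain.
        """
        picks = 0
        n_btus = 100
        for i in range(n_btus):
            guide = bk.simulate_host_tree(8, seed=500 + i)
            seqs = bk.simulate_btu_sequences(300, 8, guide, 0.02, seed=900 + i)
            _, model = genetic_distances(seqs, model="auto")
            picks += model == "JC69"
        assert picks >= 80

    def test_auto_selection_prefers_k80_on_transition_biased_data(self):
        rng = np.random.default_rng(0)
        ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
        k80_picks = 0
        for i in range(20):
            base = "".join(rng.choice(list("ACGT"), 300))
            seqs = {}
            for j in range(6):
                s = list(base)
                for pos in rng.choice(300, 25, replace=False):
                    s[pos] = ts_map[s[pos]]  # transitions only
                seqs[f"a{j}"] = "".join(s)
            _, model = genetic_distances(seqs, model="auto")
            k80_picks += model == "K80"
        assert k80_picks == 20

    def test_saturated_pairs_fall_back_to_raw(self):
        rng = np.random.default_rng(0)
        seqs = {f"a{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(4)}
        dm, model = genetic_distances(seqs, model="auto")
        assert model == "raw"
        assert np.isfinite(dm.data).all()


class TestPacoPhylogenetic:
    def test_mirrored_phylogenies_are_congruent(self):
        """1 sample/species, 1 ASV/species, ASV tree = host tree: m2 = 0."""
        tree = dendropy.Tree.get(data=ASYMMETRIC_NEWICK, schema="newick")
        coph = cophenetic_distances(tree)
        species = list(coph.ids)
        samples = [s + "_x" for s in species]
        asvs = ["asv_" + s for s in species]
        spp = pd.Series(species, index=samples)
        asv_dm = DistanceMatrix(3.0 * coph.data, asvs)  # proportional distances
        incidence = [(a, s) for a, s in zip(asvs, samples)]
        res = paco_phylogenetic(asv_dm, coph, incidence, spp, n_perm=499, seed=1)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 5 / 500  # add-one floor plus rare identity draws

    def test_too_few_occurrences_untestable(self):
        tree = bk.simulate_host_tree(4, seed=0)
        coph = cophenetic_distances(tree)
        spp = pd.Series([coph.ids[0]], index=["s0"])
        dm = DistanceMatrix(np.zeros((2, 2)), ["a0", "a1"])
        with pytest.raises(UntestableError):
            paco_phylogenetic(dm, coph, [("a0", "s0")], spp, n_perm=99, seed=0)


class TestMantel:
    def test_linear_relation_gives_r_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        ids = [str(i) for i in range(6)]
        r, _ = mantel(DistanceMatrix(d, ids), DistanceMatrix(2 * d, ids),
                      n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_p_values_are_uniform(self):
        """Independent matrices: p ~ uniform over replicates (KS at 0.01)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(1)
        ids = [str(i) for i in range(8)]
        ps = []
        for _ in range(200):
            d1 = squareform(pdist(rng.normal(size=(8, 3))))
            d2 = squareform(pdist(rng.normal(size=(8, 3))))
            _, p = mantel(DistanceMatrix(d1, ids), DistanceMatrix(d2, ids),
                          n_perm=99, seed=int(rng.integers(2**31)))
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_mantel_and_paco_effect_sizes_concord(self):
        """Across planted BTUs, Mantel r and PACo r rank alike (tau > 0)."""
        from btukit import community_distance as cd
        from btukit.reporting_pipeline import kendall_tau
        mantel_rs, paco_rs = [], []
        for seed in (1, 2, 3):
            ds, truth = bk.simulate_dataset(bk.SimulationConfig(seed=seed))
            props = cd.to_proportions(ds.counts)
            coph = cophenetic_distances(ds.tree)
            for btu in truth.btus():
                asvs = [a for a, b in truth.asv_to_btu.items() if b == btu]
                hosting = cd.btu_sample_subset(ds.counts, asvs)
                spp = ds.metadata.loc[hosting]
                gm = cd.bray_curtis(props, hosting, asvs)
                res = paco_compositional(gm, coph, spp, n_perm=99, seed=seed)
                hosting_species = sorted(set(spp))
                mean_props = props.loc[hosting, asvs].groupby(spp).mean()
                bc = DistanceMatrix(
                    squareform(pdist(mean_props.loc[hosting_species].values,
                                     metric="braycurtis")), hosting_species)
                r, _ = mantel(bc, coph.filter(hosting_species), n_perm=99,
                              seed=seed)
                mantel_rs.append(r)
                paco_rs.append(res.r)
        assert len(mantel_rs) >= 30
        tau, p = kendall_tau(mantel_rs, paco_rs)
        assert tau > 0
        assert p < 0.05


def test_sample_level_host_distance_lift():
    tree = dendropy.Tree.get(data="(A:1.0,B:2.0);", schema="newick")
    coph = cophenetic_distances(tree)
    spp = pd.Series(["A", "A", "B"], index=["s1", "s2", "s3"])
    dm = sample_level_host_distances(coph, spp)
    assert dm["s1", "s2"] == 0.0
    assert dm["s1", "s3"] == pytest.approx(3.0)
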