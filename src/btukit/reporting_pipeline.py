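"""End-to-end per-BTU analysis: binning, testing, FDR, and report tables.

For each configured binning method and community distance, the pipeline
filters the dataset, decomposes it into BTUs, applies the BTU inclusion
filters, and computes per BTU: PERMANOVA host-species specificity (R2adj),
compositional co-divergence (P_COMP), phylogenetic co-divergence (P_PHYLO,
once per BTU since it is distance-method independent), and a species-level
Mantel correlation.  Benjamini-Hochberg FDR is applied separately per
(binning method x distance x statistic) family.  A whole-community analysis
(all ASVs unpartitioned), cross-BTU Kendall-tau effect-size comparisons, the
high-specificity ASV subset permutation test, and a read/ASV accounting by
outcome category are produced alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import btu_binning, codivergence, community_distance, host_specificity
from ._rng import child_seed
from .errors import UntestableError
from .profiles_io import Dataset, cophenetic_distances, filter_samples, filter_taxa

logger = logging.getLogger(__name__)

DISTANCE_FNS = {
    "bray_curtis": community_distance.bray_curtis,
    "jaccard": community_distance.jaccard_binary,
}


@dataclass
class AnalysisConfig:
    """Pipeline-level knobs; defaults mirror the study's analysis settings."""

    binning_methods: tuple = ("genus", "sim95", "sim97")
    distance_methods: tuple = ("bray_curtis", "jaccard")
    n_perm_permanova: int = 10000
    n_perm_paco: int = 10000
    n_perm_subset: int = 9999
    n_perm_mantel: int = 999
    min_sample_reads: int = 1000
    min_btu_reads: int = 5000
    min_btu_asvs: int = 10
    fdr_alpha: float = 0.05
    high_specificity_r2adj: float = 0.2
    run_subset_test: bool = True
    subset_method: str = "genus"
    subset_distance: str = "jaccard"
    phylo_exact_perm: bool = False
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_perm_permanova, self.n_perm_paco, self.n_perm_subset):
            if n < 99:
                raise ValueError("permutation counts must be >= 99")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")


@dataclass
class ReportBundle:
    btu_tables: dict         # (method, distance) -> DataFrame of BtuReportRows
    whole_community: pd.DataFrame
    correlations: pd.DataFrame
    subset_test: dict
    accounting: pd.DataFrame
    logs: list
    metadata: dict
    partitions: dict = field(default_factory=dict)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kendall_tau(x, y) -> tuple:
    """Tie-corrected Kendall tau-b with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("kendall_tau needs paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall tau undefined for a constant vector")
    res = sps.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def _partition_for(method: str, ds: Dataset, aligned: dict) -> btu_binning.BTUPartition:
    if method == "genus":
        return btu_binning.bin_by_genus(ds.taxonomy)
    if method in ("sim95", "sim97"):
        threshold = 0.95 if method == "sim95" else 0.97
        dm = btu_binning.pairwise_distances(aligned, correction="jc")
        return btu_binning.complete_linkage_bins(dm, threshold)
    raise ValueError(f"unknown binning method {method!r}")


def _subset_alignment(aligned: dict, asvs) -> dict:
    """Restrict a global alignment to some ASVs, dropping all-gap columns."""
    sub = {a: aligned[a] for a in asvs}
    arr = np.array([list(s) for s in sub.values()])
    keep = ~(arr == "-").all(axis=0)
    return {a: "".join(np.array(list(s))[keep]) for a, s in sub.items()}


def run_pipeline(dataset: Dataset, config: AnalysisConfig) -> ReportBundle:
    """Run the full BTU-level analysis and return all report artifacts."""
    logs: list = []
    ds = filter_taxa(dataset)
    ds = filter_samples(ds, config.min_sample_reads)
    props = community_distance.to_proportions(ds.counts)
    coph = cophenetic_distances(ds.tree)
    species_of_sample = ds.metadata
    seed = config.seed

    need_alignment = any(m in ("sim95", "sim97") for m in config.binning_methods) or True
    aligned = btu_binning.align_sequences(ds.sequences) if need_alignment else {}

    btu_tables: dict = {}
    partitions: dict = {}
    total_reads = int(ds.counts.values.sum())
    total_asvs = ds.n_asvs
    accounting_rows = []

    for method in config.binning_methods:
        partition = _partition_for(method, ds, aligned)
        partition = btu_binning.filter_btus(
            partition, ds.counts, config.min_btu_reads, config.min_btu_asvs)
        partitions[method] = partition

        per_btu: dict = {}
        phylo_results: dict = {}
        for btu in sorted(partition.btus):
            asvs = [a for a in partition.btus[btu] if a in ds.counts.columns]
            hosting = community_distance.btu_sample_subset(ds.counts, asvs)
            try:
                community_distance.check_testable(hosting, species_of_sample)
            except UntestableError as exc:
                logs.append({"method": method, "btu": btu, "event": "untestable",
                             "detail": str(exc)})
                continue
            spp = species_of_sample.loc[hosting]
            genus_values = sorted(set(ds.taxonomy.loc[asvs, "genus"]))
            entry = {
                "btu": btu,
                "genus_assignment": genus_values[0] if len(genus_values) == 1
                else "ambiguous",
                "hosting_individuals": len(hosting),
                "hosting_species": int(spp.nunique()),
                "n_asvs": len(asvs),
                "asv_reads": int(ds.counts[asvs].values.sum()),
                "asvs": asvs,
                "hosting_samples": hosting,
            }

            # P_PHYLO once per BTU (distance-method independent)
            try:
                sub_aln = _subset_alignment(aligned, asvs)
                gdist, model = codivergence.genetic_distances(sub_aln, model="auto")
                if model == "raw":
                    logs.append({"method": method, "btu": btu,
                                 "event": "raw_distance_fallback", "detail": ""})
                sub_counts = ds.counts.loc[hosting, asvs]
                stacked = sub_counts.stack()
                incidence = [(a, s) for (s, a) in stacked.index[stacked > 0]]
                phylo_results[btu] = codivergence.paco_phylogenetic(
                    gdist, coph, incidence, spp,
                    n_perm=config.n_perm_paco,
                    seed=child_seed(seed, method, btu, "pphylo"),
                    btu=btu, exact_perm=config.phylo_exact_perm)
                entry["phylo_model"] = model
            except UntestableError as exc:
                logs.append({"method": method, "btu": btu,
                             "event": "pphylo_untestable", "detail": str(exc)})
                phylo_results[btu] = None
                entry["phylo_model"] = "none"

            # species-level Mantel on per-species mean proportions (Bray-Curtis)
            try:
                hosting_species = sorted(set(spp))
                mean_props = props.loc[hosting, asvs].groupby(spp).mean()
                mean_props = mean_props.loc[hosting_species]
                from scipy.spatial.distance import pdist, squareform
                from skbio import DistanceMatrix as _DM
                bc = _DM(squareform(pdist(mean_props.values, metric="braycurtis")),
                         hosting_species)
                coph_sub = coph.filter(hosting_species)
                entry["mantel_r"], entry["mantel_p"] = codivergence.mantel(
                    bc, coph_sub, n_perm=config.n_perm_mantel,
                    seed=child_seed(seed, method, btu, "mantel"))
            except (UntestableError, ValueError) as exc:
                entry["mantel_r"] = np.nan
                entry["mantel_p"] = np.nan
                logs.append({"method": method, "btu": btu,
                             "event": "mantel_untestable", "detail": str(exc)})

            per_btu[btu] = entry

        for distance in config.distance_methods:
            dist_fn = DISTANCE_FNS[distance]
            rows = []
            for btu, entry in per_btu.items():
                try:
                    dm = dist_fn(props, entry["hosting_samples"], entry["asvs"])
                    spp = species_of_sample.loc[entry["hosting_samples"]]
                    perm = host_specificity.permanova(
                        dm, spp, n_perm=config.n_perm_permanova,
                        seed=child_seed(seed, method, btu, "permanova"), btu=btu)
                    pcomp = codivergence.paco_compositional(
                        dm, coph, spp, n_perm=config.n_perm_paco,
                        seed=child_seed(seed, method, btu, "pcomp"), btu=btu)
                except UntestableError as exc:
                    logs.append({"method": method, "btu": btu,
                                 "event": f"untestable_{distance}",
                                 "detail": str(exc)})
                    continue
                pphy = phylo_results.get(btu)
                rows.append({
                    "genus_assignment": entry["genus_assignment"],
                    "btu": btu,
                    "hosting_individuals": entry["hosting_individuals"],
                    "hosting_species": entry["hosting_species"],
                    "n_asvs": entry["n_asvs"],
                    "asv_reads": entry["asv_reads"],
                    "r2": perm.r2,
                    "r2adj": perm.r2adj,
                    "permanova_p": perm.p,
                    "pcomp_r": pcomp.r,
                    "pcomp_p": pcomp.p,
                    "pphylo_r": pphy.r if pphy else np.nan,
                    "pphylo_p": pphy.p if pphy else np.nan,
                    "phylo_model": entry["phylo_model"],
                    "mantel_r": entry["mantel_r"],
                    "mantel_p": entry["mantel_p"],
                    "n_perm": config.n_perm_permanova,
                })
            table = pd.DataFrame(rows)
            if len(table):
                table = table.sort_values("btu").reset_index(drop=True)
                table["permanova_q"] = bh_fdr(table["permanova_p"])
                table["pcomp_q"] = bh_fdr(table["pcomp_p"])
                ok = table["pphylo_p"].notna()
                table["pphylo_q"] = np.nan
                if ok.any():
                    table.loc[ok, "pphylo_q"] = bh_fdr(table.loc[ok, "pphylo_p"])
                alpha = config.fdr_alpha
                table["r2adj_sig"] = table["permanova_q"] < alpha
                table["pcomp_sig"] = table["pcomp_q"] < alpha
                table["pphylo_sig"] = table["pphylo_q"] < alpha
            btu_tables[(method, distance)] = table

            # Figure-4-style accounting: every retained read/ASV lands in
            # exactly one category
            cat_asvs = dict.fromkeys(
                ("untested", "nonsignificant", "significant", "high_effect"), 0)
            cat_reads = dict.fromkeys(cat_asvs, 0)
            tested_asvs: set = set()
            for _, row in (table.iterrows() if len(table) else []):
                entry = per_btu[row["btu"]]
                sigs = [bool(row["r2adj_sig"]), bool(row["pcomp_sig"]),
                        bool(row["pphylo_sig"])]
                effects = [row["r2adj"], row["pcomp_r"],
                           row["pphylo_r"] if np.isfinite(row["pphylo_r"]) else -1]
                if any(s and e > config.high_specificity_r2adj
                       for s, e in zip(sigs, effects)):
                    cat = "high_effect"
                elif any(sigs):
                    cat = "significant"
                else:
                    cat = "nonsignificant"
                cat_asvs[cat] += entry["n_asvs"]
                cat_reads[cat] += entry["asv_reads"]
                tested_asvs.update(entry["asvs"])
            untested = [a for a in ds.counts.columns if a not in tested_asvs]
            cat_asvs["untested"] = len(untested)
            cat_reads["untested"] = int(ds.counts[untested].values.sum())
            for cat in cat_asvs:
                accounting_rows.append({
                    "method": method, "distance": distance, "category": cat,
                    "n_asvs": cat_asvs[cat], "reads": cat_reads[cat]})

    # ----- whole-community analysis (all ASVs unpartitioned) -----
    wc_rows = []
    all_asvs = list(ds.counts.columns)
    all_samples = community_distance.btu_sample_subset(ds.counts, all_asvs)
    for distance in config.distance_methods:
        dm = DISTANCE_FNS[distance](props, all_samples, all_asvs)
        spp = species_of_sample.loc[all_samples]
        perm = host_specificity.permanova(
            dm, spp, n_perm=config.n_perm_permanova,
            seed=child_seed(seed, "whole", "permanova"), btu="whole_community")
        pcomp = codivergence.paco_compositional(
            dm, coph, spp, n_perm=config.n_perm_paco,
            seed=child_seed(seed, "whole", "pcomp"), btu="whole_community")
        wc_rows.append({
            "distance": distance, "n_samples": len(all_samples),
            "r2": perm.r2, "r2adj": perm.r2adj, "permanova_p": perm.p,
            "pcomp_r": pcomp.r, "pcomp_p": pcomp.p,
        })
    whole_community = pd.DataFrame(wc_rows)

    # ----- cross-BTU effect-size concordance (Kendall tau) -----
    corr_rows = []
    for method in config.binning_methods:
        for distance in config.distance_methods:
            t = btu_tables[(method, distance)]
            if len(t) < 3:
                continue
            pairs = [("r2adj", "pcomp_r"), ("r2adj", "pphylo_r"),
                     ("pcomp_r", "pphylo_r")]
            for a, b in pairs:
                sub = t[[a, b]].dropna()
                if len(sub) >= 3 and np.ptp(sub[a]) > 0 and np.ptp(sub[b]) > 0:
                    tau, p = kendall_tau(sub[a], sub[b])
                    corr_rows.append({"method": method, "distance": distance,
                                      "x": a, "y": b, "tau": tau, "p": p,
                                      "n_btus": len(sub)})
        t_bc = btu_tables.get((method, "bray_curtis"))
        t_ja = btu_tables.get((method, "jaccard"))
        if t_bc is not None and t_ja is not None and len(t_bc) and len(t_ja):
            merged = t_bc.merge(t_ja, on="btu", suffixes=("_bc", "_ja"))
            for stat in ("r2adj", "pcomp_r"):
                a, b = merged[f"{stat}_bc"], merged[f"{stat}_ja"]
                if len(merged) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
                    tau, p = kendall_tau(a, b)
                    corr_rows.append({"method": method, "distance": "bc_vs_jaccard",
                                      "x": f"{stat}_bc", "y": f"{stat}_ja",
                                      "tau": tau, "p": p, "n_btus": len(merged)})
    correlations = pd.DataFrame(corr_rows)

    # ----- high-specificity ASV subset permutation test -----
    subset_test: dict = {"run": False}
    key = (config.subset_method, config.subset_distance)
    if config.run_subset_test and key in btu_tables and len(btu_tables[key]):
        t = btu_tables[key]
        high = t[(t["r2adj"] >= config.high_specificity_r2adj) & t["r2adj_sig"]]
        target = sorted({a for btu in high["btu"]
                         for a in partitions[config.subset_method].btus[btu]
                         if a in ds.counts.columns})
        if len(target) >= 2:
            dist_fn = DISTANCE_FNS[config.subset_distance]

            def builder(asvs):
                samples = community_distance.btu_sample_subset(ds.counts, list(asvs))
                return dist_fn(props, samples, list(asvs))

            r2adj_obs, p = host_specificity.subset_specificity_test(
                builder, all_asvs, target, species_of_sample,
                n_perm=config.n_perm_subset,
                seed=child_seed(seed, "subset_test"))
            subset_test = {
                "run": True, "n_target_asvs": len(target),
                "n_high_btus": int(len(high)), "r2adj_target": r2adj_obs,
                "p": p, "n_perm": config.n_perm_subset,
            }
        else:
            subset_test = {"run": False, "reason": "fewer than 2 high-specificity ASVs"}

    accounting = pd.DataFrame(accounting_rows)
    # conservation check: every retained read/ASV is accounted exactly once
    if len(accounting):
        for (m, d), grp in accounting.groupby(["method", "distance"]):
            assert int(grp["n_asvs"].sum()) == total_asvs
            assert int(grp["reads"].sum()) == total_reads

    metadata = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_samples": int(ds.n_samples),
        "n_species": len(ds.species),
        "n_asvs": int(total_asvs),
        "total_reads": total_reads,
    }
    return ReportBundle(btu_tables=btu_tables, whole_community=whole_community,
                        correlations=correlations, subset_test=subset_test,
                        accounting=accounting, logs=logs, metadata=metadata,
                        partitions=partitions)


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write all report artifacts as TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (method, distance), table in bundle.btu_tables.items():
        table.to_csv(outdir / f"btu_results_{method}_{distance}.tsv",
                     sep="\t", index=False, float_format="%.6g")
    bundle.whole_community.to_csv(outdir / "whole_community.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    bundle.correlations.to_csv(outdir / "effect_size_correlations.tsv", sep="\t",
                               index=False, float_format="%.6g")
    bundle.accounting.to_csv(outdir / "accounting.tsv", sep="\t", index=False)
    (outdir / "subset_test.json").write_text(json.dumps(bundle.subset_test, indent=1))
    (outdir / "run_metadata.json").write_text(json.dumps(bundle.metadata, indent=1))
    (outdir / "log.json").write_text(json.dumps(bundle.logs, indent=1))
    for method, part in bundle.partitions.items():
        rows = [{"asv": a, "btu": b, "method": method}
                for b, asvs in sorted(part.btus.items()) for a in asvs]
        pd.DataFrame(rows, columns=["asv", "btu", "method"]).to_csv(
            outdir / f"partition_{method}.tsv", sep="\t", index=False)
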