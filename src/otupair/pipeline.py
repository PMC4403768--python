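"""End-to-end orchestration: filter -> pair -> rarefy -> alpha / beta /
venn / correlation, with a counts ledger and a reproducible run log.

The stage order is fixed (rare-OTU filter, depth filter, pairing filter,
multiple rarefaction with averaging, then the analyses); a single master
seed drives rarefaction, permutation tests and jackknifing through named
substreams recorded in the log.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import alpha_diversity as alpha_mod
from . import beta_diversity as beta_mod
from .paired_correlation import (collect_paired_points, correlation_vs_threshold,
                                 dominance_census, pearson_r)
from .rarefaction import RarefactionConfig, rarefy_mean
from .tables_io import (Dataset, enforce_pairing, filter_low_depth_samples,
                        filter_rare_otus, read_metadata, read_otu_table,
                        read_taxonomy, relative_abundance, write_otu_table)
from .venn_partition import (exclusive_otu_report, partition_by_site,
                             top_abundance_table)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize_counts"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialised into the report."""

    table_path: str
    metadata_path: str
    outdir: str
    tree_path: str | None = None
    taxonomy_path: str | None = None
    min_otu_reads: int = 10
    min_otu_samples: int = 5
    otu_filter_mode: str = "or"
    min_sample_depth: int = 1000
    rarefaction_depth: int | None = None
    rarefaction_reps: int = 100
    permutations: int = 100_000
    jackknife_replicates: int = 100
    thresholds: tuple = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0, 50.0)
    metrics: tuple = ("bray_curtis", "jaccard")
    alpha_base: float = 2.0
    seed: int = 0
    make_plots: bool = True


@dataclass
class RunReport:
    """Artifacts and bookkeeping from one pipeline run."""

    paths: dict[str, str]
    ledger: pd.DataFrame
    log: list[str] = field(default_factory=list)


def _seeds(master: int) -> dict[str, int]:
    """Named substreams derived from the master seed (kept below 2**31)."""
    ss = np.random.SeedSequence(master)
    names = ("rarefaction", "alpha_perm", "adonis", "jackknife")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def summarize_counts(stages: list[tuple[str, Dataset]]) -> pd.DataFrame:
    """Ledger of OTUs / samples / birds / reads surviving each stage,
    pooled and per trial."""
    rows = []
    trials = sorted({s.trial for _, d in stages for s in d.samples})
    for name, d in stages:
        row = {"stage": name,
               "otus": d.table.shape[0],
               "samples": d.table.shape[1],
               "birds": len(d.birds()),
               "reads": float(d.table.counts.sum())}
        for t in trials:
            row[f"samples_{t}"] = sum(1 for s in d.samples if s.trial == t)
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in fixed order and write all artifacts to outdir."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    seeds = _seeds(cfg.seed)
    log: list[str] = [f"seed={cfg.seed}", f"substreams={seeds}",
                      f"config={asdict(cfg)}"]
    paths: dict[str, str] = {}

    def out(name: str) -> str:
        paths[name] = os.path.join(cfg.outdir, name)
        return paths[name]

    # ---- load ------------------------------------------------------------
    table = read_otu_table(cfg.table_path)
    samples = read_metadata(cfg.metadata_path)
    taxonomy = read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None
    tree = None
    if cfg.tree_path:
        from skbio import TreeNode
        tree = TreeNode.read(cfg.tree_path, convert_underscores=False)
    dataset = Dataset(table=table, samples=samples, taxonomy=taxonomy)
    stages = [("input", dataset)]
    log.append(f"input: {table.shape[0]} OTUs x {table.shape[1]} samples")

    # ---- filters ---------------------------------------------------------
    filtered = filter_rare_otus(table, cfg.min_otu_reads, cfg.min_otu_samples,
                                mode=cfg.otu_filter_mode)
    dataset = dataset.with_table(filtered)
    stages.append(("otu_filter", dataset))
    log.append(f"otu_filter({cfg.otu_filter_mode}): kept {filtered.shape[0]} "
               f"OTUs")

    depth_res = filter_low_depth_samples(dataset, cfg.min_sample_depth)
    dataset = depth_res.dataset
    stages.append(("depth_filter", dataset))
    log.append(f"depth_filter: removed {len(depth_res.dropped_sample_ids)} "
               f"samples {depth_res.dropped_sample_ids}")

    before = set(dataset.table.sample_ids)
    dataset = enforce_pairing(dataset)
    removed_mates = sorted(before - set(dataset.table.sample_ids))
    stages.append(("pairing_filter", dataset))
    log.append(f"pairing_filter: removed {len(removed_mates)} unpaired "
               f"samples {removed_mates}; total removed with mates = "
               f"{len(depth_res.dropped_sample_ids) + len(removed_mates)}")

    raw = dataset  # integer counts, used for venn and integer alpha indices

    # ---- rarefaction -----------------------------------------------------
    rcfg = RarefactionConfig(depth=cfg.rarefaction_depth,
                             repetitions=cfg.rarefaction_reps,
                             seed=seeds["rarefaction"])
    averaged = rarefy_mean(dataset.table, rcfg)
    avg_dataset = dataset.with_table(averaged)
    stages.append(("rarefied_mean", avg_dataset))
    depth_used = float(averaged.counts.sum(axis=0)[0])
    log.append(f"rarefy_mean: depth={depth_used:g} reps={cfg.rarefaction_reps}")
    write_otu_table(averaged, out("rarefied_table.tsv"))

    # ---- alpha -----------------------------------------------------------
    frac_alpha = alpha_mod.alpha_table(averaged, tree=tree, base=cfg.alpha_base)
    # singleton-based estimators: per-rarefaction means on integer draws
    int_alpha = alpha_mod.alpha_per_rarefaction(
        raw.table, RarefactionConfig(depth=cfg.rarefaction_depth,
                                     repetitions=cfg.rarefaction_reps,
                                     seed=seeds["rarefaction"]))
    alpha_df = frac_alpha.drop(columns=["singles", "doubles", "chao1"],
                               errors="ignore").join(int_alpha)
    alpha_df.to_csv(out("alpha_diversity.tsv"), sep="\t")
    comparisons = []
    for idx in alpha_df.columns:
        vals = alpha_df[idx].dropna()
        if vals.size < alpha_df.shape[0]:
            continue
        comp = alpha_mod.compare_sites_alpha(
            vals, dataset.samples, index_name=idx,
            permutations=cfg.permutations, seed=seeds["alpha_perm"])
        comparisons.append(comp)
    comp_df = pd.DataFrame([{
        "index": c.index_name, "mean_cecal": c.mean_cecal,
        "mean_fecal": c.mean_fecal, "observed_diff": c.observed_diff,
        "permutations": c.permutations, "p_value": c.p_value,
        "p": c.p_label, "statistic": c.statistic,
        "bonferroni_p": min(1.0, c.p_value * max(1, len(alpha_df.columns))),
    } for c in comparisons])
    comp_df.to_csv(out("alpha_comparisons.tsv"), sep="\t", index=False)
    log.append(f"alpha: {len(comparisons)} indices compared, "
               f"permutations={cfg.permutations}")

    # ---- beta ------------------------------------------------------------
    groups = [dataset.site_of(s) for s in averaged.sample_ids]
    adonis_rows = []
    dms = {}
    for metric in cfg.metrics:
        dm = beta_mod.pairwise_distance(averaged, metric)
        dms[metric] = dm
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out(f"distance_{metric}.tsv"), sep="\t")
    if tree is not None:
        dms["unweighted_unifrac"] = beta_mod.unweighted_unifrac(averaged, tree)
        dms["weighted_unifrac"] = beta_mod.weighted_unifrac(averaged, tree)
        for name in ("unweighted_unifrac", "weighted_unifrac"):
            dm = dms[name]
            pd.DataFrame(dm.data, index=list(dm.ids),
                         columns=list(dm.ids)).to_csv(
                out(f"distance_{name}.tsv"), sep="\t")
    for name, dm in dms.items():
        res = beta_mod.adonis(dm, groups, permutations=cfg.permutations,
                              seed=seeds["adonis"])
        adonis_rows.append({"distance": name, "pseudo_F": res.pseudo_F,
                            "R2": res.R2, "permutations": res.permutations,
                            "p_value": res.p_value, "p": res.p_label})
    pd.DataFrame(adonis_rows).to_csv(out("adonis.tsv"), sep="\t", index=False)
    ord_dm = dms.get("weighted_unifrac", dms[cfg.metrics[0]])
    ordination = beta_mod.pcoa(ord_dm)
    ordination.coordinates.to_csv(out("pcoa_coordinates.tsv"), sep="\t")
    with open(out("upgma.nwk"), "w") as fh:
        fh.write(beta_mod.upgma(ord_dm) + "\n")
    if tree is not None:
        jk = beta_mod.jackknife_unifrac(
            raw, tree, replicates=cfg.jackknife_replicates,
            seed=seeds["jackknife"])
        with open(out("jackknife_upgma.nwk"), "w") as fh:
            fh.write(jk.newick + "\n")
        log.append(f"jackknife: {jk.replicates} replicates at depth "
                   f"{jk.depth}")
    log.append(f"adonis: {len(adonis_rows)} distance matrices tested")

    # ---- venn & top tables ----------------------------------------------
    cecal_fecal = set(raw.sites()) == {"cecal", "fecal"}
    if cecal_fecal:
        part = partition_by_site(raw)
        with open(out("venn.json"), "w") as fh:
            json.dump(part.as_dict(), fh, indent=1)
        if taxonomy is not None:
            excl, excl_summary = exclusive_otu_report(part, raw)
            excl.to_csv(out("exclusive_otus.tsv"), sep="\t", index=False)
            with open(out("exclusive_summary.json"), "w") as fh:
                json.dump(excl_summary, fh, indent=1)
        for site in ("cecal", "fecal"):
            top = top_abundance_table(avg_dataset, site)
            top.to_csv(out(f"top20_{site}.tsv"), sep="\t")
        log.append(f"venn: pct_otus={part.pct_otus} "
                   f"pct_sequences={part.pct_sequences}")

        # ---- paired correlation ------------------------------------------
        points = collect_paired_points(avg_dataset)
        points.to_csv(out("paired_points.tsv"), sep="\t", index=False)
        curves = []
        trials = [None] + avg_dataset.trials()
        for axis in ("cecal_min", "fecal_min"):
            for trial in trials:
                c = correlation_vs_threshold(points, site_axis=axis,
                                             thresholds=cfg.thresholds,
                                             trial=trial)
                for t, r, npts in zip(c.thresholds, c.r_values, c.n_points):
                    curves.append({"site_axis": axis, "trial": c.trial,
                                   "threshold_pct": t, "r": r,
                                   "n_points": npts})
        curve_df = pd.DataFrame(curves)
        curve_df.to_csv(out("correlation_curves.tsv"), sep="\t", index=False)
        census = dominance_census(points)
        with open(out("dominance.json"), "w") as fh:
            json.dump({"birds_with_cecal_dominant": census[0],
                       "birds_with_fecal_dominant": census[1],
                       "cutoff_pct": 50.0}, fh, indent=1)
        log.append(f"correlation: r(all)={pearson_r(points):.4f}, "
                   f"dominance census={census}")
        if cfg.make_plots:
            _plot_curves(curve_df, out("correlation_curves.png"))

    # ---- ledger & log ----------------------------------------------------
    ledger = summarize_counts(stages)
    ledger.to_csv(out("counts_ledger.tsv"), sep="\t")
    with open(out("run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return RunReport(paths=paths, ledger=ledger, log=log)


def _plot_curves(curve_df: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    colours = {"cecal_min": "red", "fecal_min": "blue"}
    for (axis, trial), sub in curve_df.groupby(["site_axis", "trial"]):
        style = "-" if trial == "all" else "--"
        ax.plot(sub["threshold_pct"], sub["r"], style,
                color=colours[axis], alpha=1.0 if trial == "all" else 0.4,
                label=f"{axis} {trial}" if trial == "all" else None)
    ax.set_xlabel("minimum abundance threshold (%)")
    ax.set_ylabel("Pearson r (cecal vs fecal)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
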