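"""Three-way partition of OTUs by site occupancy and the reports built
on it: the shared/exclusive Venn summary (by OTU count and by sequence
mass), the exclusive-OTU taxonomy report, and the top-N abundance tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import Dataset, relative_abundance

__all__ = ["VennPartition", "partition_by_site", "exclusive_otu_report",
           "top_abundance_table"]


@dataclass
class VennPartition:
    """Shared / cecal-only / fecal-only split of OTUs and read mass.

    ``pct_otus`` and ``pct_sequences`` are (shared, cecal_only, fecal_only)
    percentages; each triple sums to 100.
    """

    shared_otus: list[str]
    cecal_only_otus: list[str]
    fecal_only_otus: list[str]
    pct_otus: tuple[float, float, float]
    pct_sequences: tuple[float, float, float]

    def as_dict(self) -> dict:
        return {
            "n_shared": len(self.shared_otus),
            "n_cecal_only": len(self.cecal_only_otus),
            "n_fecal_only": len(self.fecal_only_otus),
            "pct_otus": {"shared": round(self.pct_otus[0], 2),
                         "cecal_only": round(self.pct_otus[1], 2),
                         "fecal_only": round(self.pct_otus[2], 2)},
            "pct_sequences": {"shared": round(self.pct_sequences[0], 2),
                              "cecal_only": round(self.pct_sequences[1], 2),
                              "fecal_only": round(self.pct_sequences[2], 2)},
        }


def partition_by_site(dataset: Dataset,
                      presence_threshold: float = 0.0) -> VennPartition:
    """Partition OTUs by detection in the two sites.

    An OTU is site-exclusive when its total abundance exceeds
    ``presence_threshold`` in at least one sample of that site and in no
    sample of the other; otherwise it is shared.  Sequence percentages use
    total reads across all samples as denominator.  Detection is normally
    assessed on the raw post-filter counts (threshold 0); pass a positive
    threshold when running on rarefaction-averaged tables.
    """
    sites = dataset.sites()
    pair = ("cecal", "fecal") if "cecal" in sites or "fecal" in sites \
        else ("ceca_left", "ceca_right")
    for site in pair:
        if site not in sites:
            raise ValueError(f"site {site!r} has no samples in the dataset")
    a_cols = dataset.samples_for_site(pair[0])
    b_cols = dataset.samples_for_site(pair[1])
    df = dataset.table.to_dataframe()
    in_a = (df[a_cols] > presence_threshold).any(axis=1)
    in_b = (df[b_cols] > presence_threshold).any(axis=1)
    shared = df.index[in_a & in_b].tolist()
    a_only = df.index[in_a & ~in_b].tolist()
    b_only = df.index[~in_a & in_b].tolist()
    n = len(shared) + len(a_only) + len(b_only)
    if n == 0:
        raise ValueError("no detected OTUs to partition")
    total_reads = float(df.to_numpy().sum())
    reads = {k: float(df.loc[v].to_numpy().sum())
             for k, v in (("shared", shared), ("a", a_only), ("b", b_only))}
    # full precision here; percentages are rounded to 2 decimals only in
    # exported reports so the three-way split always sums to 100 exactly
    pct_otus = tuple(100.0 * len(v) / n for v in (shared, a_only, b_only))
    pct_seq = tuple(100.0 * reads[k] / total_reads
                    for k in ("shared", "a", "b"))
    return VennPartition(shared_otus=shared, cecal_only_otus=a_only,
                         fecal_only_otus=b_only, pct_otus=pct_otus,
                         pct_sequences=pct_seq)


def exclusive_otu_report(partition: VennPartition, dataset: Dataset,
                         similarity_threshold: float = 97.0
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-OTU report for the site-exclusive OTUs.

    Each row: site, total reads, mean relative abundance (%) in its own
    site, closest isolate and % similarity, and whether the similarity
    exceeds ``similarity_threshold`` (a proxy for "matches a known type
    strain").  The summary gives, per site, the percentage of exclusive
    OTUs above the threshold among those with taxonomy, and counts the
    unannotated ones separately.
    """
    if dataset.taxonomy is None:
        raise ValueError("exclusive_otu_report requires taxonomy annotations")
    df = dataset.table.to_dataframe()
    rel = relative_abundance(dataset.table).to_dataframe()
    rows = []
    for site_name, otus in (("cecal", partition.cecal_only_otus),
                            ("fecal", partition.fecal_only_otus)):
        cols = dataset.samples_for_site(site_name)
        for otu in otus:
            tax = dataset.taxonomy.get(otu)
            rows.append({
                "otu_id": otu,
                "site": site_name,
                "total_reads": float(df.loc[otu].sum()),
                "mean_rel_abundance_pct": float(rel.loc[otu, cols].mean()),
                "isolate": tax[0] if tax else None,
                "similarity": tax[1] if tax else None,
                "above_threshold": (tax[1] > similarity_threshold)
                if tax else None,
            })
    report = pd.DataFrame(rows, columns=["otu_id", "site", "total_reads",
                                         "mean_rel_abundance_pct", "isolate",
                                         "similarity", "above_threshold"])
    summary = {}
    for site_name in ("cecal", "fecal"):
        sub = report[report.site == site_name]
        annotated = sub[sub.similarity.notna()]
        summary[site_name] = {
            "n_exclusive": int(len(sub)),
            "n_without_taxonomy": int(sub.similarity.isna().sum()),
            "pct_above_threshold": (
                round(100.0 * annotated.above_threshold.sum()
                      / len(annotated), 2) if len(annotated) else None),
        }
    return report, summary


def top_abundance_table(dataset: Dataset, site: str,
                        n: int = 20) -> pd.DataFrame:
    """The ``n`` most abundant OTUs of ``site`` with both sites' shares.

    Abundance is the OTU's percentage of the site's total reads (summed
    over the site's samples), computed from the same table for both site
    columns so shared OTUs appear with consistent values whichever site
    ranks them.  Ties break by OTU id.
    """
    sites = dataset.sites()
    if site not in sites:
        raise ValueError(f"site {site!r} not present (have {sites})")
    df = dataset.table.to_dataframe()
    pct = {}
    for s in sites:
        cols = dataset.samples_for_site(s)
        tot = df[cols].to_numpy().sum()
        if tot == 0:
            raise ValueError(f"site {s!r} has zero reads")
        pct[s] = 100.0 * df[cols].sum(axis=1) / tot
    if n > len(df.index):
        warnings.warn(f"requested top {n} but only {len(df.index)} OTUs; "
                      f"returning all")
        n = len(df.index)
    order = pd.DataFrame({"pct": pct[site]}).sort_values(
        by="pct", ascending=False, kind="mergesort")
    # mergesort is stable; pre-sorting the index makes ties break by OTU id
    order = order.loc[sorted(df.index)].sort_values(
        by="pct", ascending=False, kind="mergesort")
    top = order.index[:n]
    out = pd.DataFrame({"otu_id": top})
    for s in sites:
        out[f"pct_in_{s}"] = pct[s].loc[top].to_numpy()
    if dataset.taxonomy:
        out["isolate"] = [dataset.taxonomy.get(o, (None, None))[0]
                          for o in top]
        out["similarity"] = [dataset.taxonomy.get(o, (None, None))[1]
                             for o in top]
    out["rank"] = np.arange(1, len(top) + 1)
    return out.set_index("rank")
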