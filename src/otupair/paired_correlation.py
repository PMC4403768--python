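"""Abundance-stratified correlation between paired cecal and fecal
communities.

For every (bird, OTU) pair where the OTU is detected in both of the
bird's samples, the per-sample relative abundances form one point;
Pearson r over those points, recomputed while raising a minimum-abundance
threshold on one axis, traces how inter-site agreement decays from the
rare biosphere to the dominant OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import Dataset, pair_map, relative_abundance

__all__ = ["collect_paired_points", "pearson_r", "CorrelationCurve",
           "correlation_vs_threshold", "dominance_census"]

POINT_COLUMNS = ["bird_id", "otu_id", "trial", "cecal_pct", "fecal_pct"]


def collect_paired_points(dataset: Dataset,
                          detection_floor: float = 0.0) -> pd.DataFrame:
    """One row per (bird, OTU) with positive abundance in both samples.

    Expects a post-filter, paired dataset (typically rarefaction-averaged).
    Abundances are percentages of each sample's reads.  OTUs at or below
    ``detection_floor`` in either sample of a bird are excluded for that
    bird, matching the "present in both samples" rule.
    """
    pairs = pair_map(dataset)
    bad = [b for b, m in pairs.items() if set(m) != {"cecal", "fecal"}]
    if bad:
        raise ValueError(f"unpaired birds (run enforce_pairing first): {bad}")
    rel = relative_abundance(dataset.table).to_dataframe()
    trial_of = {s.bird_id: s.trial for s in dataset.samples}
    rows = []
    for bird, m in pairs.items():
        c = rel[m["cecal"]]
        f = rel[m["fecal"]]
        keep = (c > detection_floor) & (f > detection_floor)
        for otu in rel.index[keep]:
            rows.append((bird, otu, trial_of[bird], c[otu], f[otu]))
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def pearson_r(points: pd.DataFrame, method: str = "pearson",
              log10: bool = False) -> float:
    """Correlation of cecal vs fecal abundance over the point set.

    Returns NaN (not an exception) when fewer than 3 points remain or an
    axis has zero variance.  ``method`` may be ``"pearson"`` (default) or
    ``"spearman"``; ``log10`` correlates log10 abundances instead.
    """
    if len(points) < 3:
        return float("nan")
    x = points["cecal_pct"].to_numpy(dtype=float)
    y = points["fecal_pct"].to_numpy(dtype=float)
    if log10:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CorrelationCurve:
    """Pearson r as a function of a minimum-abundance threshold."""

    site_axis: str               # "cecal_min" or "fecal_min"
    thresholds: list[float]      # ascending, percent scale
    r_values: list[float]        # NaN where < 3 points remain
    n_points: list[int]
    trial: str = "all"
    method: str = "pearson"


DEFAULT_THRESHOLDS = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0, 50.0)


def correlation_vs_threshold(points: pd.DataFrame,
                             site_axis: str = "cecal_min",
                             thresholds=DEFAULT_THRESHOLDS,
                             trial: str | None = None,
                             method: str = "pearson",
                             log10: bool = False) -> CorrelationCurve:
    """Correlation restricted to points above a rising abundance floor.

    ``site_axis`` selects which site's abundance must be >= the threshold
    (``cecal_min`` or ``fecal_min``); ``trial`` restricts to one trial.
    At threshold 0 the curve reproduces ``pearson_r`` of the full set.
    """
    if site_axis not in ("cecal_min", "fecal_min"):
        raise ValueError("site_axis must be 'cecal_min' or 'fecal_min'")
    thresholds = [float(t) for t in thresholds]
    if not thresholds or any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be non-empty and ascending")
    if trial is not None:
        points = points[points["trial"] == trial]
    col = "cecal_pct" if site_axis == "cecal_min" else "fecal_pct"
    r_values, n_points = [], []
    for t in thresholds:
        sub = points[points[col] >= t]
        n_points.append(int(len(sub)))
        r_values.append(pearson_r(sub, method=method, log10=log10))
    return CorrelationCurve(site_axis=site_axis, thresholds=thresholds,
                            r_values=r_values, n_points=n_points,
                            trial=trial if trial is not None else "all",
                            method=method)


def dominance_census(points: pd.DataFrame,
                     cutoff_pct: float = 50.0) -> tuple[int, int]:
    """Birds carrying at least one OTU above ``cutoff_pct`` per site.

    Returns (birds with a > cutoff cecal OTU, birds with a > cutoff fecal
    OTU); a bird can appear in both counts.
    """
    if len(points) == 0:
        return 0, 0
    cecal = points.loc[points["cecal_pct"] > cutoff_pct, "bird_id"].nunique()
    fecal = points.loc[points["fecal_pct"] > cutoff_pct, "bird_id"].nunique()
    return int(cecal), int(fecal)
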