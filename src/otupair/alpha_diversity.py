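"""Within-sample (alpha) diversity indices and the site comparison test.

Indices: observed species, singleton/doubleton counts, bias-corrected
Chao1, Shannon entropy (base 2 by default), Simpson evenness, Pielou-type
equitability, Strong's dominance index and Faith's phylogenetic diversity.
Counts-only estimators that depend on singletons (F1/F2, Chao1) are
defined only on integer vectors; the proportion-based indices also accept
fractional rarefaction-averaged input.

Sites are compared with a Monte-Carlo permutation test on the absolute
difference of site means; with ``permutations`` relabelings the smallest
attainable p-value is 1/permutations, reported with a "< 1/permutations"
label when no permuted statistic reaches the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import Dataset, OtuTable, SampleRecord

__all__ = [
    "AlphaComparison",
    "observed_species",
    "singles_doubles",
    "chao1",
    "shannon",
    "simpson_evenness",
    "equitability",
    "strong_dominance",
    "faith_pd",
    "alpha_table",
    "compare_sites_alpha",
]

INTEGER_INDICES = ("singles", "doubles", "chao1")
ALL_INDICES = ("observed_species", "singles", "doubles", "chao1", "shannon",
               "simpson_evenness", "equitability", "strong_dominance",
               "faith_pd")


def _as_vector(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if v.size == 0 or np.any(v < 0):
        raise ValueError("abundance vector must be non-empty and non-negative")
    return v


def _require_positive(v: np.ndarray) -> np.ndarray:
    if v.sum() <= 0:
        raise ValueError("abundance vector has no positive entries")
    return v


def _require_integer(v: np.ndarray) -> np.ndarray:
    if np.any(np.abs(v - np.round(v)) > 1e-9):
        raise ValueError(
            "integer counts required; for rarefaction-averaged tables compute "
            "this index per rarefaction and average the results")
    return np.round(v)


def observed_species(counts, threshold: float = 0.0) -> int:
    """Number of OTUs with abundance strictly above ``threshold``."""
    v = _as_vector(counts)
    return int((v > threshold).sum())


def singles_doubles(counts) -> tuple[int, int]:
    """(F1, F2): number of OTUs with count exactly 1 and exactly 2."""
    v = _require_integer(_as_vector(counts))
    return int((v == 1).sum()), int((v == 2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    v = _require_integer(_as_vector(counts))
    s_obs = observed_species(v)
    f1, f2 = singles_doubles(v)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_base p_i over positive p_i."""
    v = _require_positive(_as_vector(counts))
    p = v[v > 0] / v.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson_evenness(counts) -> float:
    """Simpson evenness E = (1/D) / S_obs with D = sum p_i^2."""
    v = _require_positive(_as_vector(counts))
    p = v[v > 0] / v.sum()
    d = float((p ** 2).sum())
    return (1.0 / d) / p.size


def equitability(counts, base: float = 2.0) -> float:
    """Equitability J = H / log_base(S_obs); 1 by convention when S_obs = 1."""
    v = _require_positive(_as_vector(counts))
    s_obs = observed_species(v)
    if s_obs == 1:
        return 1.0
    return shannon(v, base=base) / (np.log(s_obs) / np.log(base))


def strong_dominance(counts) -> float:
    """Strong's dominance D_w = max_i (b_i/N - i/S_obs).

    ``b_i`` is the cumulative count of the i most abundant OTUs; a uniform
    community scores 0, a single runaway dominant pushes the index toward 1.
    """
    v = _require_positive(_as_vector(counts))
    v = np.sort(v[v > 0])[::-1]
    n = v.sum()
    s = v.size
    ranks = np.arange(1, s + 1)
    return float(np.max(np.cumsum(v) / n - ranks / s))


def faith_pd(counts, otu_ids: Sequence[str], tree) -> float:
    """Faith's PD: branch length of the minimal subtree spanning the
    observed OTUs and the root of ``tree`` (an skbio TreeNode)."""
    v = _as_vector(counts)
    if len(otu_ids) != v.size:
        raise ValueError("otu_ids and counts length mismatch")
    observed = {str(o) for o, c in zip(otu_ids, v) if c > 0}
    if not observed:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(observed - tip_names)
    if missing:
        raise ValueError(f"observed OTUs missing from tree: {missing}")
    total = 0.0
    # post-order: a branch counts when at least one observed tip is below it
    has_obs: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            flag = node.name in observed
        else:
            flag = any(has_obs[id(c)] for c in node.children)
        has_obs[id(node)] = flag
        if flag and node.parent is not None and node.length is not None:
            total += node.length
    return float(total)


def alpha_table(table: OtuTable, tree=None,
                indices: Iterable[str] | None = None,
                base: float = 2.0,
                threshold: float = 0.0) -> pd.DataFrame:
    """Alpha-diversity table: one row per sample, one column per index.

    Integer-only indices (singles, doubles, chao1) are skipped with a NaN
    column when the table is fractional; compute them per-rarefaction
    instead.  ``faith_pd`` requires ``tree``.
    """
    if indices is None:
        indices = [i for i in ALL_INDICES if i != "faith_pd" or tree is not None]
    indices = list(indices)
    integer_ok = table.is_integer()
    rows = {}
    for sample in table.sample_ids:
        v = table.sample_vector(sample)
        row = {}
        for name in indices:
            if name in INTEGER_INDICES and not integer_ok:
                row[name] = np.nan
                continue
            if name == "observed_species":
                row[name] = observed_species(v, threshold)
            elif name == "singles":
                row[name] = singles_doubles(v)[0]
            elif name == "doubles":
                row[name] = singles_doubles(v)[1]
            elif name == "chao1":
                row[name] = chao1(v)
            elif name == "shannon":
                row[name] = shannon(v, base=base)
            elif name == "simpson_evenness":
                row[name] = simpson_evenness(v)
            elif name == "equitability":
                row[name] = equitability(v, base=base)
            elif name == "strong_dominance":
                row[name] = strong_dominance(v)
            elif name == "faith_pd":
                if tree is None:
                    raise ValueError("faith_pd requires a tree")
                row[name] = faith_pd(v, table.otu_ids, tree)
            else:
                raise ValueError(f"unknown alpha index {name!r}")
        rows[sample] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df[indices]


def alpha_per_rarefaction(table: OtuTable, config, tree=None,
                          indices: Iterable[str] = INTEGER_INDICES,
                          base: float = 2.0) -> pd.DataFrame:
    """Mean of an alpha index over repeated single rarefactions.

    The singleton-based estimators (F1, F2, Chao1) are undefined on a
    rarefaction-averaged table, so they are computed on each integer
    rarefaction draw and the per-sample values averaged.  ``config`` is a
    :class:`~otupair.rarefaction.RarefactionConfig`.
    """
    from .rarefaction import rarefy_once, _resolve_depth
    depth = _resolve_depth(table, config.depth)
    rng = np.random.default_rng(config.seed)
    acc = None
    for _ in range(config.repetitions):
        sub = rarefy_once(table, depth, rng)
        df = alpha_table(sub, tree=tree, indices=list(indices), base=base)
        acc = df if acc is None else acc + df
    return acc / config.repetitions


@dataclass
class AlphaComparison:
    """Permutation comparison of one alpha index between the two sites."""

    index_name: str
    mean_cecal: float
    mean_fecal: float
    observed_diff: float
    permutations: int
    p_value: float
    p_label: str
    at_floor: bool
    statistic: str = "abs_mean_difference"


def _permutation_p(count_ge: int, permutations: int) -> tuple[float, str, bool]:
    if count_ge == 0:
        return 1.0 / permutations, f"< {1.0 / permutations:g}", True
    p = count_ge / permutations
    return p, f"{p:g}", False


def compare_sites_alpha(values: Mapping[str, float] | pd.Series,
                        samples: Sequence[SampleRecord],
                        index_name: str = "",
                        permutations: int = 100_000,
                        seed: int = 0,
                        paired: bool = False) -> AlphaComparison:
    """Monte-Carlo permutation test of an index between the two sites.

    The observed statistic is |mean(site A) - mean(site B)|.  The default
    null permutes site labels freely across samples; ``paired=True``
    instead flips the sign of each bird's within-pair difference
    (a paired two-sided test).  p = (# permuted >= observed)/permutations,
    floored at 1/permutations.
    """
    values = pd.Series(values)
    by_site: dict[str, list[float]] = {}
    bird_site: dict[str, dict[str, float]] = {}
    for s in samples:
        if s.sample_id not in values.index:
            raise ValueError(f"no {index_name or 'index'} value for sample "
                             f"{s.sample_id!r}")
        by_site.setdefault(s.site, []).append(float(values[s.sample_id]))
        bird_site.setdefault(s.bird_id, {})[s.site] = float(values[s.sample_id])
    sites = sorted(by_site)
    if len(sites) != 2:
        raise ValueError(f"expected exactly 2 sites, got {sites}")
    a, b = (np.asarray(by_site[s], dtype=float) for s in sites)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each site needs at least 2 samples")
    mean_a, mean_b = a.mean(), b.mean()
    observed = abs(mean_a - mean_b)
    rng = np.random.default_rng(seed)
    count_ge = 0
    if paired:
        diffs = np.array([d[sites[0]] - d[sites[1]]
                          for d in bird_site.values() if len(d) == 2])
        if diffs.size == 0:
            raise ValueError("paired test requires complete pairs")
        obs_paired = abs(diffs.mean())
        for start in range(0, permutations, 20_000):
            m = min(20_000, permutations - start)
            signs = rng.choice([-1.0, 1.0], size=(m, diffs.size))
            stat = np.abs((signs * diffs).mean(axis=1))
            count_ge += int((stat >= obs_paired - 1e-12).sum())
        observed = obs_paired
    else:
        pooled = np.concatenate([a, b])
        n, n_a = pooled.size, a.size
        for start in range(0, permutations, 5_000):
            m = min(5_000, permutations - start)
            order = rng.random((m, n)).argsort(axis=1)
            perm = pooled[order]
            stat = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
            count_ge += int((stat >= observed - 1e-12).sum())
    p, label, floor = _permutation_p(count_ge, permutations)
    site_mean = dict(zip(sites, (mean_a, mean_b)))
    return AlphaComparison(
        index_name=index_name,
        mean_cecal=site_mean.get("cecal", site_mean.get("ceca_left", mean_a)),
        mean_fecal=site_mean.get("fecal", site_mean.get("ceca_right", mean_b)),
        observed_diff=float(observed),
        permutations=permutations,
        p_value=p, p_label=label, at_floor=floor,
        statistic="abs_mean_paired_difference" if paired
        else "abs_mean_difference")
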