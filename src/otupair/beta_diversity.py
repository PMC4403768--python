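"""Between-sample (beta) diversity: distances, UniFrac, ordination,
clustering and PERMANOVA-style inference.

The eight non-phylogenetic metrics follow the legacy QIIME conventions
(Canberra averaged over non-zero coordinate pairs, "Pearson" = 1 - r),
UniFrac is computed from branch incidence over a rooted tree, PERMANOVA
(ADONIS) partitions squared distances with a label-permutation null,
PCoA is classical scaling of the Gower-centred matrix, and UPGMA is
average-linkage agglomeration with lexicographic tie-breaking.  Distance
matrices are skbio ``DistanceMatrix`` objects (symmetric, zero diagonal,
id-aware).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .rarefaction import rarefy_once
from .tables_io import Dataset, OtuTable

__all__ = [
    "METRICS",
    "pairwise_distance",
    "unweighted_unifrac",
    "weighted_unifrac",
    "AdonisResult",
    "adonis",
    "PcoaResult",
    "pcoa",
    "upgma",
    "JackknifeResult",
    "jackknife_unifrac",
]

METRICS = ("jaccard", "bray_curtis", "canberra", "chord", "euclidean",
           "manhattan", "pearson", "soergel")


# ---------------------------------------------------------------------------
# non-phylogenetic metrics
# ---------------------------------------------------------------------------

def _metric_value(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "jaccard":
        ax, ay = x > 0, y > 0
        union = np.logical_or(ax, ay).sum()
        if union == 0:
            return 0.0
        inter = np.logical_and(ax, ay).sum()
        return 1.0 - inter / union
    if metric == "bray_curtis":
        denom = (x + y).sum()
        return 0.0 if denom == 0 else float(np.abs(x - y).sum() / denom)
    if metric == "canberra":
        # legacy convention: mean of |x-y|/(x+y) over coordinates where
        # x + y > 0, not the raw sum
        nz = (x + y) > 0
        if not nz.any():
            return 0.0
        return float((np.abs(x - y)[nz] / (x + y)[nz]).mean())
    if metric == "chord":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError("chord distance undefined for an all-zero sample")
        return float(np.linalg.norm(x / nx - y / ny))
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "manhattan":
        return float(np.abs(x - y).sum())
    if metric == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("pearson distance undefined for a constant sample")
        r = np.corrcoef(x, y)[0, 1]
        return float(1.0 - r)
    if metric == "soergel":
        denom = np.maximum(x, y).sum()
        return 0.0 if denom == 0 else float(np.abs(x - y).sum() / denom)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def pairwise_distance(table: OtuTable, metric: str) -> DistanceMatrix:
    """All-pairs sample distances under one of the eight metrics."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = table.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    counts = table.counts
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _metric_value(counts[:, i], counts[:, j], metric)
    # clip float noise so identical columns give an exact 0
    d[np.abs(d) < 1e-15] = 0.0
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _branch_incidence(tree: TreeNode, otu_ids: Sequence[str],
                      observed_mask: np.ndarray):
    """Branch incidence of a rooted tree over the table's OTUs.

    Returns (lengths, incidence) where ``incidence[b, i]`` is True when
    OTU i descends from branch b.  Every OTU flagged in ``observed_mask``
    must be a tip of the tree; tree tips absent from the table contribute
    branches with no observed descendants (harmless zeros).
    """
    idx = {str(o): i for i, o in enumerate(otu_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(o for o, keep in zip(otu_ids, observed_mask)
                     if keep and str(o) not in tip_names)
    if missing:
        raise ValueError(f"OTUs with nonzero counts missing from tree: "
                         f"{missing}")
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    n = len(otu_ids)
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(n, dtype=bool)
            if node.name in idx:
                mask[idx[node.name]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for c in node.children:
                mask |= below[id(c)]
        below[id(node)] = mask
        if node.parent is not None:
            lengths.append(node.length if node.length is not None else 0.0)
            rows.append(mask)
    return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / (unique + shared) branch length,
    restricted to branches leading to at least one observed OTU."""
    counts = table.counts
    observed_any = counts.sum(axis=1) > 0
    lengths, inc = _branch_incidence(tree, table.otu_ids, observed_any)
    present = counts > 0  # (n_otus, n_samples)
    # branch b "present" in sample j iff any observed descendant
    branch_present = inc.astype(float) @ present.astype(float) > 0
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = branch_present[:, i], branch_present[:, j]
            either = pi | pj
            unique = pi ^ pj
            denom = lengths[either].sum()
            d[i, j] = d[j, i] = (0.0 if denom == 0
                                 else lengths[unique].sum() / denom)
    return DistanceMatrix(d, table.sample_ids)


def weighted_unifrac(table: OtuTable, tree: TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac on per-sample proportions.

    raw = sum_b l_b |p_b^X - p_b^Y| where p_b is the fraction of the
    community descending from branch b; the normalised variant divides by
    sum_b l_b (p_b^X + p_b^Y) and is bounded in [0, 1].
    """
    counts = table.counts
    depths = counts.sum(axis=0)
    zero = [s for s, dep in zip(table.sample_ids, depths) if dep == 0]
    if zero:
        raise ValueError(f"zero-depth samples: {zero}")
    observed_any = counts.sum(axis=1) > 0
    lengths, inc = _branch_incidence(tree, table.otu_ids, observed_any)
    props = counts / depths
    # one post-order accumulation per sample, shared across all pairs
    branch_prop = inc.astype(float) @ props  # (n_branches, n_samples)
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = branch_prop[:, i], branch_prop[:, j]
            raw = float((lengths * np.abs(pi - pj)).sum())
            if normalized:
                denom = float((lengths * (pi + pj)).sum())
                raw = 0.0 if denom == 0 else raw / denom
            d[i, j] = d[j, i] = raw
    d[np.abs(d) < 1e-15] = 0.0
    return DistanceMatrix(d, table.sample_ids)


# ---------------------------------------------------------------------------
# ADONIS / PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class AdonisResult:
    """One-factor PERMANOVA on a distance matrix."""

    pseudo_F: float
    R2: float
    permutations: int
    p_value: float
    p_label: str
    at_floor: bool
    ss_total: float
    ss_between: float
    ss_within: float


def _ss_within(d2: np.ndarray, labels: np.ndarray,
               groups: np.ndarray) -> float:
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def adonis(dm: DistanceMatrix, groups: Sequence[str],
           permutations: int = 100_000, seed: int = 0,
           strata: Sequence[str] | None = None) -> AdonisResult:
    """One-factor PERMANOVA (ADONIS) with a permutation null.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous
    within-group terms; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
    Labels are permuted freely, or within ``strata`` blocks (e.g. trials)
    when given.  p respects the 1/permutations floor convention.
    """
    labels = np.asarray([str(g) for g in groups])
    n = len(dm.ids)
    if labels.size != n:
        raise ValueError("groups must align with the distance matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"singleton groups not allowed: {small}")
    a = uniq.size
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray([str(s) for s in strata])
        if strata.size != n:
            raise ValueError("strata must align with the distance matrix ids")
        blocks = [np.flatnonzero(strata == b) for b in np.unique(strata)]
    count_ge = 0
    masks = [labels == g for g in uniq]
    chunk = max(1, min(permutations, 2_000_000 // max(n * n, 1)))
    done = 0
    while done < permutations:
        m = min(chunk, permutations - done)
        if strata is None:
            order = rng.random((m, n)).argsort(axis=1)
        else:
            order = np.tile(np.arange(n), (m, 1))
            for idx in blocks:
                sub = rng.random((m, idx.size)).argsort(axis=1)
                order[:, idx] = idx[sub]
        ssw_perm = np.zeros(m)
        for g_mask, n_g in zip(masks, counts):
            memb = g_mask[order]  # (m, n) permuted membership
            ssw_perm += np.einsum("ci,ij,cj->c", memb, d2, memb) / (2.0 * n_g)
        ssb_perm = ss_total - ssw_perm
        f_perm = (ssb_perm / (a - 1)) / (ssw_perm / (n - a))
        count_ge += int((f_perm >= f_obs - 1e-12).sum())
        done += m
    if count_ge == 0:
        p, label, floor = 1.0 / permutations, f"< {1.0 / permutations:g}", True
    else:
        p = count_ge / permutations
        label, floor = f"{p:g}", False
    return AdonisResult(pseudo_F=float(f_obs), R2=float(r2),
                        permutations=permutations, p_value=p, p_label=label,
                        at_floor=floor, ss_total=float(ss_total),
                        ss_between=float(ss_between),
                        ss_within=float(ss_within))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray    # positive eigenvalues, descending
    negative_eigenvalue_mass: float  # sum|neg| / sum|all|


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates: eigendecomposition of the double-centred
    -D^2/2 matrix.  Axes with negative eigenvalues are dropped and their
    relative magnitude reported; no Lingoes/Cailliez correction."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tiny = 1e-10 * max(1.0, float(np.abs(evals).max() or 1.0))
    pos = evals > tiny
    neg_mass_num = float(np.abs(evals[evals < -tiny]).sum())
    denom = float(np.abs(evals).sum())
    neg_mass = 0.0 if denom == 0 else neg_mass_num / denom
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=evals[pos],
        negative_eigenvalue_mass=neg_mass)


# ---------------------------------------------------------------------------
# UPGMA and jackknifing
# ---------------------------------------------------------------------------

def _upgma(dm: DistanceMatrix):
    """Average-linkage agglomeration.

    Returns (newick, clades, heights): ``clades`` is the set of frozensets
    of leaf names below each internal node, ``heights`` maps each clade to
    its merge height.  Ties are broken by the lexicographically smallest
    (min-leaf, max-leaf) label pair, so output is deterministic.
    """
    ids = list(dm.ids)
    dist: dict[frozenset, float] = {}
    data = np.asarray(dm.data, dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[frozenset((ids[i], ids[j]))] = data[i, j]
    active: dict[str, dict] = {
        s: {"newick": s, "height": 0.0, "size": 1, "leaves": frozenset((s,))}
        for s in ids}
    clades: set[frozenset] = set()
    heights: dict[frozenset, float] = {}
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                d = dist[frozenset((a, b))]
                key = (d, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, a, b) = best[0], best[1], best[2]
        ca, cb = active.pop(a), active.pop(b)
        d = dist[frozenset((a, b))]
        h = d / 2.0
        la = h - ca["height"]
        lb = h - cb["height"]
        first, second = ((ca, la), (cb, lb)) if a < b else ((cb, lb), (ca, la))
        newick = (f"({first[0]['newick']}:{first[1]:.10g},"
                  f"{second[0]['newick']}:{second[1]:.10g})")
        leaves = ca["leaves"] | cb["leaves"]
        name = min(leaves)
        clades.add(leaves)
        heights[leaves] = h
        for other in active:
            key_a, key_b = frozenset((a, other)), frozenset((b, other))
            d_new = (ca["size"] * dist[key_a] + cb["size"] * dist[key_b]) / (
                ca["size"] + cb["size"])
            dist[frozenset((name, other))] = d_new
        active[name] = {"newick": newick, "height": h,
                        "size": ca["size"] + cb["size"], "leaves": leaves}
    root = next(iter(active.values()))
    return root["newick"] + ";", clades, heights


def upgma(dm: DistanceMatrix) -> str:
    """UPGMA (average linkage) clustering of samples; ultrametric Newick."""
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 samples")
    return _upgma(dm)[0]


@dataclass
class JackknifeResult:
    """Jackknifed UniFrac clustering: consensus tree plus clade supports."""

    newick: str                      # majority consensus with support labels
    master_newick: str               # full-depth UPGMA tree, for reference
    support: dict[frozenset, float]  # consensus clade -> replicate fraction
    replicates: int
    depth: int


def jackknife_unifrac(dataset: Dataset, tree: TreeNode,
                      depth_fraction: float = 0.75,
                      replicates: int = 100,
                      weighted: bool = True,
                      seed: int = 0) -> JackknifeResult:
    """Support values for UniFrac/UPGMA sample clustering.

    Each replicate rarefies every sample (without replacement) to
    ``depth_fraction`` x the minimum sample depth and recomputes UniFrac
    and UPGMA.  Clades recurring in more than half the replicates form the
    majority-rule consensus tree (such clades are always mutually
    compatible); each carries the fraction of replicates reproducing it as
    its support label.  The full-depth UPGMA tree is kept for reference.
    """
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must be in (0, 1]")
    table = dataset.table
    if not table.is_integer():
        raise ValueError("jackknifing requires an integer (raw or single-"
                         "rarefaction) table")
    depth = int(np.floor(depth_fraction * table.counts.sum(axis=0).min()))
    if depth < 1:
        raise ValueError(f"infeasible jackknife depth {depth}")
    metric = weighted_unifrac if weighted else unweighted_unifrac
    master_newick, _, _ = _upgma(metric(table, tree))
    counts: dict[frozenset, int] = {}
    children = np.random.SeedSequence(seed).spawn(replicates)
    for ss in children:
        rng = np.random.default_rng(ss)
        sub = rarefy_once(table, depth, rng)
        _, clades, _ = _upgma(metric(sub, tree))
        for c in clades:
            counts[c] = counts.get(c, 0) + 1
    support = {c: k / replicates for c, k in counts.items()
               if k / replicates > 0.5}
    all_leaves = frozenset(table.sample_ids)
    consensus = _consensus_newick(all_leaves, support)
    return JackknifeResult(newick=consensus, master_newick=master_newick,
                           support=support, replicates=replicates,
                           depth=depth)


def _consensus_newick(leaves: frozenset,
                      support: dict[frozenset, float]) -> str:
    """Topology-only Newick of the nested majority clades, with supports
    as internal node labels."""

    def build(clade: frozenset) -> str:
        subs = [c for c in support if c < clade]
        maximal = [c for c in subs if not any(c < d for d in subs)]
        covered: set = set().union(*maximal) if maximal else set()
        parts = [build(c) + f"{support[c]:.2f}" for c in sorted(
            maximal, key=lambda c: min(c))]
        parts += sorted(clade - covered)
        return "(" + ",".join(parts) + ")"

    root_label = f"{support[leaves]:.2f}" if leaves in support else ""
    return build(leaves) + root_label + ";"
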