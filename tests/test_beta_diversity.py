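import io
import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova

import otupair as op
from otupair.beta_diversity import _metric_value


def _table(arr, otu_ids=None, sample_ids=None):
    arr = np.asarray(arr, dtype=float)
    return op.OtuTable(arr,
                       otu_ids=otu_ids or [f"o{i}" for i in range(arr.shape[0])],
                       sample_ids=sample_ids or [f"s{j}"
                                                 for j in range(arr.shape[1])])


# ---------------------------------------------------------------------------
# non-phylogenetic metrics
# ---------------------------------------------------------------------------

def test_identical_columns_give_zero_everywhere():
    t = _table([[3, 3], [1, 1], [7, 7]])
    for metric in op.METRICS:
        assert op.pairwise_distance(t, metric).data[0, 1] == 0.0


def test_disjoint_supports_maximal():
    t = _table([[5, 0], [2, 0], [0, 3]])
    for metric in ("jaccard", "bray_curtis", "soergel"):
        assert op.pairwise_distance(t, metric).data[0, 1] == pytest.approx(1.0)


def test_hand_worked_metric_values():
    x, y = np.array([1.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0])
    assert _metric_value(x, y, "jaccard") == pytest.approx(2 / 3, abs=1e-12)
    assert _metric_value(x, y, "bray_curtis") == pytest.approx(0.5)
    assert _metric_value(x, y, "manhattan") == pytest.approx(2.0)
    assert _metric_value(x, y, "euclidean") == pytest.approx(np.sqrt(2))
    # canberra averages |x-y|/(x+y) over the 3 nonzero-sum coordinates
    assert _metric_value(x, y, "canberra") == pytest.approx(2 / 3)
    assert _metric_value(x, y, "soergel") == pytest.approx(2 / 3)


def test_pearson_and_errors():
    t = _table([[1, 2], [2, 4], [3, 8]])
    d = op.pairwise_distance(t, "pearson").data[0, 1]
    assert 0 <= d <= 2
    with pytest.raises(ValueError):
        op.pairwise_distance(_table([[1, 1], [1, 2]]), "pearson")
    with pytest.raises(ValueError):
        op.pairwise_distance(t, "nope")


def test_metrics_agree_with_reference_library():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 30, (12, 5)).astype(float)
    t = _table(counts)
    for mine, theirs in (("bray_curtis", "braycurtis"),
                         ("euclidean", "euclidean"),
                         ("manhattan", "cityblock")):
        ref = beta_diversity(theirs, counts.T, ids=t.sample_ids).data
        np.testing.assert_allclose(op.pairwise_distance(t, mine).data, ref,
                                   atol=1e-12)


def test_distance_axioms_on_random_tables():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 20, (15, 6)).astype(float) + 0.0
    counts[:, 0] += 1  # avoid constant column for pearson
    t = _table(counts)
    for metric in op.METRICS:
        d = op.pairwise_distance(t, metric).data
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def test_unweighted_unifrac_hand_cases():
    star = TreeNode.read(io.StringIO("(A:1,B:1,C:1);"))
    t = _table([[1, 0], [0, 1], [0, 0]], otu_ids=["A", "B", "C"])
    assert op.unweighted_unifrac(t, star).data[0, 1] == pytest.approx(1.0)
    nested = TreeNode.read(io.StringIO("((A:1,B:1):1);"))
    t2 = _table([[1, 1], [1, 0]], otu_ids=["A", "B"])
    assert op.unweighted_unifrac(t2, nested).data[0, 1] == pytest.approx(
        1 / 3, abs=1e-12)
    # identical presence -> 0
    t3 = _table([[1, 2], [3, 1]], otu_ids=["A", "B"])
    assert op.unweighted_unifrac(t3, nested).data[0, 1] == 0.0


def test_weighted_unifrac_hand_cases_and_scale_invariance():
    star = TreeNode.read(io.StringIO("(A:1,B:1,C:1);"))
    t = _table([[10, 0], [0, 5], [0, 0]], otu_ids=["A", "B", "C"])
    assert op.weighted_unifrac(t, star).data[0, 1] == pytest.approx(1.0)
    t2 = _table([[4, 8], [6, 12]], otu_ids=["A", "B"])
    cherry = TreeNode.read(io.StringIO("(A:1,B:1);"))
    # proportional columns -> distance 0 under proportions
    assert op.weighted_unifrac(t2, cherry).data[0, 1] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        op.weighted_unifrac(_table([[0, 1]], otu_ids=["A"]),
                            TreeNode.read(io.StringIO("(A:1,B:1);")))


def test_unifrac_missing_leaf_error():
    tree = TreeNode.read(io.StringIO("(A:1,B:1);"))
    t = _table([[1, 0], [0, 1]], otu_ids=["A", "Z"])
    with pytest.raises(ValueError, match="Z"):
        op.unweighted_unifrac(t, tree)


def test_unifrac_matches_reference_library():
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 40, (20, 8)).astype(float)
    counts[:, 0] += 1
    ids = [f"O{i}" for i in range(20)]
    t = _table(counts, otu_ids=ids)
    tree = op.generate_tree(20, seed=4, ids=ids)
    for weighted in (False, True):
        mine = (op.weighted_unifrac if weighted
                else op.unweighted_unifrac)(t, tree).data
        name = "weighted_unifrac" if weighted else "unweighted_unifrac"
        kw = {"normalized": True} if weighted else {}
        ref = beta_diversity(name, counts.T.astype(int), ids=t.sample_ids,
                             taxa=ids, tree=tree, **kw).data
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        assert mine.max() <= 1.0 + 1e-12 and mine.min() >= 0.0


# ---------------------------------------------------------------------------
# ADONIS
# ---------------------------------------------------------------------------

def test_adonis_partition_identity_and_reference_f():
    rng = np.random.default_rng(1)
    counts = rng.integers(1, 50, (10, 8)).astype(float)
    dm = op.pairwise_distance(_table(counts), "bray_curtis")
    groups = ["a"] * 4 + ["b"] * 4
    res = op.adonis(dm, groups, permutations=999, seed=0)
    assert res.R2 + res.ss_within / res.ss_total == pytest.approx(1.0,
                                                                  abs=1e-9)
    ref = permanova(DistanceMatrix(dm.data, dm.ids), grouping=groups,
                    permutations=0)
    assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-9)


def test_adonis_separated_clusters():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 0.01, (10, 3))
    b = rng.normal(1, 0.01, (10, 3)) + [10, 0, 0]
    pts = np.vstack([a, b])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    dm = DistanceMatrix(d, [f"s{i}" for i in range(20)])
    res = op.adonis(dm, ["a"] * 10 + ["b"] * 10, permutations=1000, seed=3)
    assert res.R2 > 0.9
    assert res.at_floor


def test_adonis_small_n_matches_exhaustive_enumeration():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(6, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"s{i}" for i in range(6)]
    dm = DistanceMatrix(d, ids)
    labels = np.array(["a", "a", "a", "b", "b", "b"])

    def pseudo_f(lab):
        d2 = d ** 2
        ss_tot = d2.sum() / 12
        ssw = 0.0
        for g in ("a", "b"):
            idx = np.flatnonzero(lab == g)
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
        return (ss_tot - ssw) / (ssw / 4)

    obs = pseudo_f(labels)
    count = 0
    for idx in itertools.combinations(range(6), 3):
        lab = np.array(["b"] * 6)
        lab[list(idx)] = "a"
        count += pseudo_f(lab) >= obs - 1e-12
    exact = count / 20
    res = op.adonis(dm, labels, permutations=20_000, seed=7)
    assert res.p_value == pytest.approx(exact, abs=0.02)


def test_adonis_errors_and_strata():
    d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                       ["a", "b", "c"])
    with pytest.raises(ValueError):
        op.adonis(d, ["g1", "g1", "g2"], permutations=10)
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(8, 2))
    dd = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    dm = DistanceMatrix(dd, [f"s{i}" for i in range(8)])
    res = op.adonis(dm, ["a", "b"] * 4, permutations=500, seed=1,
                    strata=["t1"] * 4 + ["t2"] * 4)
    assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# PCoA and UPGMA
# ---------------------------------------------------------------------------

def test_pcoa_collinear_and_duplicates():
    d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                       ["a", "b", "c"])
    res = op.pcoa(d)
    c = res.coordinates["PC1"]
    assert abs(c["a"] - c["b"]) == pytest.approx(1.0, abs=1e-9)
    assert abs(c["a"] - c["c"]) == pytest.approx(2.0, abs=1e-9)
    assert len(res.eigenvalues) == 1  # second axis is numerically zero
    dup = DistanceMatrix(np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float),
                         ["a", "b", "c"])
    r2 = op.pcoa(dup)
    np.testing.assert_allclose(r2.coordinates.loc["a"],
                               r2.coordinates.loc["b"], atol=1e-9)


def test_pcoa_exact_on_euclidean_distances():
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(9, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    res = op.pcoa(DistanceMatrix(d, [f"s{i}" for i in range(9)]))
    emb = res.coordinates.to_numpy()
    d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
    np.testing.assert_allclose(d_emb, d, atol=1e-6)
    assert res.negative_eigenvalue_mass == pytest.approx(0.0, abs=1e-9)


def test_upgma_hand_cases_and_ultrametricity():
    two = DistanceMatrix(np.array([[0, 3], [3, 0]], float), ["A", "B"])
    assert op.upgma(two) == "(A:1.5,B:1.5);"
    three = DistanceMatrix(np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float),
                           ["A", "B", "C"])
    assert op.upgma(three) == "((A:1,B:1):3,C:4);"
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(7, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    nwk = op.upgma(DistanceMatrix(d, [f"s{i}" for i in range(7)]))
    tree = TreeNode.read(io.StringIO(nwk))
    depths = [tree.distance(t) for t in tree.tips()]
    assert max(depths) - min(depths) < 1e-8


def test_jackknife_support():
    # single replicate -> every master clade has support 1.0
    rng = np.random.default_rng(5)
    cfg = op.GeneratorConfig(n_birds=4, n_otus=40, seed=15,
                             low_depth_bird_fraction=0.0)
    ds, _ = op.generate_paired_dataset(cfg)
    tree = op.generate_tree(len(ds.table.otu_ids), seed=1,
                            ids=ds.table.otu_ids)
    jk = op.jackknife_unifrac(ds, tree, replicates=1, seed=2)
    assert all(v == 1.0 for v in jk.support.values())
    jk2 = op.jackknife_unifrac(ds, tree, replicates=10, seed=2)
    assert set(jk2.support.values()) <= {k / 10 for k in range(11)}
    assert "0." in jk2.newick or "1.00" in jk2.newick


def test_jackknife_recovers_strong_site_split():
    # strongly separated site communities: the cecal/fecal bipartition
    # of the UPGMA tree should be reproduced in >= 95% of replicates
    cfg = op.GeneratorConfig(n_birds=5, n_otus=60, seed=21,
                             low_depth_bird_fraction=0.0,
                             lognormal_sigma_cecal=1.0,
                             lognormal_sigma_fecal=1.0,
                             site_profile_correlation=-0.5)
    ds, _ = op.generate_paired_dataset(cfg)
    tree = op.generate_tree(len(ds.table.otu_ids), seed=2,
                            ids=ds.table.otu_ids)
    jk = op.jackknife_unifrac(ds, tree, replicates=40, seed=3)
    cecal = frozenset(s.sample_id for s in ds.samples if s.site == "cecal")
    fecal = frozenset(s.sample_id for s in ds.samples if s.site == "fecal")
    splits = {c: v for c, v in jk.support.items() if c in (cecal, fecal)}
    assert splits, "site bipartition absent from master tree"
    assert max(splits.values()) >= 0.95
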