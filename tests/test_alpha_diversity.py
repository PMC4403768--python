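import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode
from skbio.diversity.alpha import chao1 as sk_chao1, shannon as sk_shannon

import otupair as op


# ---------------------------------------------------------------------------
# index values
# ---------------------------------------------------------------------------

def test_observed_species_with_threshold():
    assert op.observed_species([5, 0, 1, 0]) == 2
    assert op.observed_species([0, 0]) == 0
    assert op.observed_species([0.02, 3.1]) == 2
    assert op.observed_species([0.02, 3.1], threshold=0.5) == 1


def test_singles_doubles():
    assert op.singles_doubles([1, 1, 2, 5]) == (2, 1)
    assert op.singles_doubles([3, 5]) == (0, 0)
    assert op.singles_doubles([1, 2, 1, 2, 1]) == (3, 2)
    with pytest.raises(ValueError, match="per rarefaction"):
        op.singles_doubles([1.2, 2.0])


def test_chao1_closed_form():
    assert op.chao1([5, 3, 1, 1]) == pytest.approx(5.0, abs=1e-12)
    assert op.chao1([5, 3, 3]) == 3  # no singletons -> collapses to S_obs


def test_shannon_and_equitability():
    assert op.shannon([1, 1, 1, 1]) == pytest.approx(2.0, abs=1e-12)
    assert op.shannon([7]) == pytest.approx(0.0, abs=1e-12)
    assert op.shannon([75, 25]) == pytest.approx(0.8112781245, abs=1e-9)
    assert op.equitability([75, 25]) == pytest.approx(0.8112781245, abs=1e-9)
    assert op.equitability([3, 3, 3]) == pytest.approx(1.0, abs=1e-12)
    assert op.equitability([9]) == 1.0  # convention for S_obs = 1
    with pytest.raises(ValueError):
        op.shannon([0, 0])


def test_simpson_evenness():
    assert op.simpson_evenness([4, 4, 4, 4]) == pytest.approx(1.0, abs=1e-12)
    assert op.simpson_evenness([5]) == pytest.approx(1.0, abs=1e-12)
    assert op.simpson_evenness([90, 10]) == pytest.approx(1 / 0.82 / 2,
                                                          abs=1e-9)


def test_strong_dominance():
    assert op.strong_dominance([2, 2, 2, 2]) == pytest.approx(0.0, abs=1e-12)
    assert op.strong_dominance([97, 1, 1, 1]) == pytest.approx(0.72, abs=1e-12)
    # moving mass from the rarest to the most abundant OTU raises dominance
    assert op.strong_dominance([90, 6, 3, 1]) < op.strong_dominance(
        [91, 6, 3, 0.5])


def test_faith_pd():
    tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))
    assert op.faith_pd([1, 1, 0], ["A", "B", "C"], tree) == pytest.approx(3.0)
    assert op.faith_pd([1, 1, 1], ["A", "B", "C"], tree) == pytest.approx(5.0)
    assert op.faith_pd([0, 0, 1], ["A", "B", "C"], tree) == pytest.approx(2.0)
    with pytest.raises(ValueError, match="D"):
        op.faith_pd([1], ["D"], tree)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=2, max_size=30).filter(
    lambda v: sum(v) > 0), st.randoms(use_true_random=False))
def test_indices_invariant_to_otu_order_and_chao_bound(v, rnd):
    shuffled = list(v)
    rnd.shuffle(shuffled)
    for f in (op.observed_species, op.shannon, op.simpson_evenness,
              op.equitability, op.strong_dominance, op.chao1):
        assert f(v) == pytest.approx(f(shuffled), abs=1e-9)
    assert op.chao1(v) >= op.observed_species(v)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 40), min_size=3, max_size=25).filter(
    lambda v: sum(v) > 0))
def test_chao1_and_shannon_match_reference_library(v):
    arr = np.array(v)
    assert op.chao1(arr) == pytest.approx(sk_chao1(arr, bias_corrected=True))
    assert op.shannon(arr) == pytest.approx(sk_shannon(arr, base=2))


# ---------------------------------------------------------------------------
# site comparison
# ---------------------------------------------------------------------------

def _records(n_per_site):
    recs = []
    for k in range(n_per_site):
        recs.append(op.SampleRecord(f"c{k}", f"b{k}", "cecal", "t1"))
        recs.append(op.SampleRecord(f"f{k}", f"b{k}", "fecal", "t1"))
    return recs


def test_no_signal_gives_large_p():
    vals = {}
    for k in range(6):
        vals[f"c{k}"] = float(k)
        vals[f"f{k}"] = float(k)
    res = op.compare_sites_alpha(vals, _records(6), "shannon",
                                 permutations=2000, seed=1)
    assert res.p_value >= 0.9


def test_perfect_separation_hits_floor():
    vals = {f"c{k}": 10.0 for k in range(12)} | {f"f{k}": 0.0
                                                 for k in range(12)}
    res = op.compare_sites_alpha(vals, _records(12), "chao1",
                                 permutations=100_000, seed=2)
    assert res.at_floor
    assert res.p_value == pytest.approx(1e-5)
    assert res.p_label.startswith("<")


def test_small_n_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    vals = {f"c{k}": float(rng.normal(1.0)) for k in range(3)}
    vals |= {f"f{k}": float(rng.normal(0.0)) for k in range(3)}
    pooled = np.array(list(vals.values()))
    obs = abs(pooled[:3].mean() - pooled[3:].mean())
    count = 0
    for idx in itertools.combinations(range(6), 3):
        rest = [i for i in range(6) if i not in idx]
        stat = abs(pooled[list(idx)].mean() - pooled[rest].mean())
        count += stat >= obs - 1e-12
    exact = count / 20
    res = op.compare_sites_alpha(vals, _records(3), "x",
                                 permutations=20_000, seed=3)
    assert res.p_value == pytest.approx(exact, abs=0.02)


def test_paired_mode_runs_and_detects_shift():
    rng = np.random.default_rng(4)
    vals = {}
    for k in range(10):
        base = rng.normal()
        vals[f"c{k}"] = base + 1.0
        vals[f"f{k}"] = base
    res = op.compare_sites_alpha(vals, _records(10), "shannon",
                                 permutations=5000, seed=5, paired=True)
    assert res.p_value < 0.01
    assert res.statistic == "abs_mean_paired_difference"


def test_singleton_site_rejected():
    recs = [op.SampleRecord("c0", "b0", "cecal", "t"),
            op.SampleRecord("f0", "b0", "fecal", "t"),
            op.SampleRecord("f1", "b1", "fecal", "t")]
    with pytest.raises(ValueError):
        op.compare_sites_alpha({"c0": 1, "f0": 2, "f1": 3}, recs, "x",
                               permutations=10, seed=0)


def test_alpha_table_integer_indices_nan_on_fractional():
    t = op.OtuTable(np.array([[1.5, 2.0], [0.5, 1.0]]),
                    otu_ids=["a", "b"], sample_ids=["s1", "s2"])
    df = op.alpha_table(t)
    assert df["chao1"].isna().all()
    assert np.isfinite(df["shannon"]).all()
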