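"""Cohort statistics: totals, test oracles (closed-form Welch, rank-sum
enumeration, BH step-up), size factors, sharing set algebra, the simple
differential test's calibration and power, and the cell-type rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from circnigra import (
    BackspliceJunction, CircCountMatrix, bh_adjust, celltype_call,
    circ_totals_per_sample, expressed_by_region, pearson_correlation,
    sharing_summary, simple_de, size_factors, two_group_test,
)


def _matrix(data: dict[str, list], samples: list[str], mapped=None):
    keys = sorted(data)
    junctions = [BackspliceJunction("c1", 10 * (i + 1), 10 * (i + 1) + 5, "+")
                 for i in range(len(keys))]
    df = pd.DataFrame(dict(zip(samples, zip(*[data[k] for k in keys]))),
                      index=[j.key for j in junctions])
    if mapped is None:
        mapped = {s: max(int(df[s].sum()), 1) * 10 for s in samples}
    return CircCountMatrix(junctions=junctions, counts=df,
                           mapped_totals=pd.Series(mapped))


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

def test_circ_totals_modes_and_scale_invariance():
    mat = _matrix({"a": [2, 0], "b": [0, 0], "c": [5, 0]}, ["s1", "s2"],
                  mapped={"s1": 2_000_000, "s2": 1_000_000})
    distinct = circ_totals_per_sample(mat, mode="distinct")
    reads = circ_totals_per_sample(mat, mode="reads")
    assert distinct["s1"] == 2 and reads["s1"] == 7
    norm = circ_totals_per_sample(mat, mode="reads", normalized=True)
    assert norm["s1"] == pytest.approx(3.5)
    deeper = _matrix({"a": [4, 0], "b": [0, 0], "c": [10, 0]}, ["s1", "s2"],
                     mapped={"s1": 4_000_000, "s2": 2_000_000})
    norm2 = circ_totals_per_sample(deeper, mode="reads", normalized=True)
    assert np.allclose(norm, norm2)


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def test_welch_t_against_closed_form():
    a = np.array([1.1, 2.3, 3.2, 2.8, 1.9])
    b = np.array([4.0, 5.5, 4.8, 6.1])
    res = two_group_test(a, b, method="t")
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    assert res.statistic == pytest.approx(t)
    assert res.p_value == pytest.approx(p)
    strong = two_group_test([1, 2, 3], [101, 102, 103], method="t")
    assert strong.p_value < 0.001


def test_welch_zero_variance_flag():
    res = two_group_test([2, 2, 2], [2, 2, 2], method="t")
    assert res.p_value == 1.0 and res.flag == "zero-variance"
    assert res.statistic == 0.0


def test_wilcoxon_exact_small_sample_enumeration():
    """a=(1,2) vs b=(3,4): all C(4,2)=6 rank splits, one as extreme."""
    res = two_group_test([1, 2], [3, 4], method="wilcoxon")
    assert res.p_value == pytest.approx(2 / 6)
    ident = two_group_test([1, 2, 3], [1, 2, 3], method="wilcoxon")
    assert ident.p_value >= 0.95


def test_pearson_correlation_limits_and_flags():
    assert pearson_correlation([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert pearson_correlation([1, 2, 3, 4], [4, 3, 2, 1]).r == pytest.approx(
        -1.0)
    flat = pearson_correlation([1, 1, 1], [2, 3, 4])
    assert not flat.defined
    with pytest.raises(ValueError):
        pearson_correlation([1, 2], [3, 4])


def test_pearson_null_pvalues_uniform():
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(400):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        ps.append(pearson_correlation(x, y).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def test_bh_hand_example_and_edge_cases():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
    assert np.allclose(bh_adjust([0.2]), [0.2])
    assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    assert bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=40))
def test_bh_equals_bruteforce_stepup(ps):
    assert np.allclose(bh_adjust(ps), _bh_bruteforce(ps))


# ---------------------------------------------------------------------------
# sharing
# ---------------------------------------------------------------------------

def test_sharing_summary_set_algebra_oracle():
    rng = np.random.default_rng(4)
    regions = ["SN", "MTG", "AMG"]
    member = pd.DataFrame(rng.random((10, 3)) < 0.5, columns=regions,
                          index=[f"j{i}" for i in range(10)])
    summ = sharing_summary(member)
    # brute-force set algebra
    sets = {r: set(member.index[member[r]]) for r in regions}
    expressed = set().union(*sets.values())
    assert summ.n_features == len(expressed)
    for f in expressed:
        combo = frozenset(r for r in regions if f in sets[r])
        assert summ.cells[combo] >= 1
    only_sn = {f for f in expressed
               if f in sets["SN"] and f not in sets["MTG"]
               and f not in sets["AMG"]}
    assert summ.unique_counts["SN"] == len(only_sn)
    all_shared = sets["SN"] & sets["MTG"] & sets["AMG"]
    assert summ.shared_all == len(all_shared)
    assert sum(summ.cells.values()) == summ.n_features
    pw = summ.pairwise_shared[("SN", "MTG")]
    assert pw == len(sets["SN"] & sets["MTG"])


def test_expressed_by_region_rules():
    mat = _matrix({"a": [3, 3, 0], "b": [0, 1, 0]}, ["sn1", "sn2", "mtg1"])
    meta = pd.DataFrame({"region": ["SN", "SN", "MTG"]},
                        index=["sn1", "sn2", "mtg1"])
    circ_rule = expressed_by_region(mat, meta, rule="tissue_reads",
                                    min_reads=5)
    mrna_rule = expressed_by_region(mat, meta, rule="any_count")
    a_key, b_key = sorted(mat.counts.index)[0], sorted(mat.counts.index)[1]
    assert bool(circ_rule.loc[mat.counts.index[0], "SN"])  # 6 reads > 5
    assert not bool(circ_rule.loc[mat.counts.index[1], "SN"])  # 1 read
    assert bool(mrna_rule.loc[mat.counts.index[1], "SN"])


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_hand_examples_and_equivariance():
    counts = pd.DataFrame({"s1": [2, 4], "s2": [8, 16]})
    sf = size_factors(counts)
    assert sf["s1"] == pytest.approx(0.5)
    assert sf["s2"] == pytest.approx(2.0)
    same = size_factors(pd.DataFrame({"s1": [3, 7, 9], "s2": [3, 7, 9]}))
    assert np.allclose(same, 1.0)
    # scaling one sample by c scales its factor relative to the others by c
    # (the absolute factors shift by c^(1/n) through the geometric-mean
    # reference, as in the DESeq convention)
    scaled = counts.copy()
    scaled["s1"] = scaled["s1"] * 5
    sf2 = size_factors(scaled)
    assert sf2["s1"] / sf2["s2"] == pytest.approx(5 * sf["s1"] / sf["s2"])
    with pytest.raises(ValueError):
        size_factors(pd.DataFrame({"s1": [0, 2], "s2": [3, 0]}))


def test_size_factors_match_pydeseq2():
    """Cross-check the median-of-ratios step against pydeseq2 on a random
    matrix (features x samples; pydeseq2 uses samples x features)."""
    from pydeseq2.preprocessing import deseq2_norm

    rng = np.random.default_rng(10)
    counts = pd.DataFrame(rng.poisson(50, size=(60, 5)) + 1,
                          columns=[f"s{i}" for i in range(5)])
    _norm, ref = deseq2_norm(counts.T)
    assert np.allclose(size_factors(counts).to_numpy(),
                       np.asarray(ref).ravel())


# ---------------------------------------------------------------------------
# simple differential test
# ---------------------------------------------------------------------------

def _cohort_matrix(rng, n_feat=60, n_per=8, fold=None, hot=0):
    base = rng.lognormal(3.0, 1.0, size=n_feat)
    lam = np.tile(base[:, None], (1, 2 * n_per))
    if fold is not None:
        lam[:hot, n_per:] *= fold
    counts = rng.poisson(lam)
    samples = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"f{i}" for i in range(n_feat)])
    junctions = [BackspliceJunction("c1", 10 * i + 1, 10 * i + 6, "+")
                 for i in range(n_feat)]
    df.index = [j.key for j in junctions]
    mat = CircCountMatrix(junctions=junctions, counts=df,
                          mapped_totals=df.sum(axis=0) * 10)
    meta = pd.DataFrame({"condition": ["CT"] * n_per + ["PD"] * n_per},
                        index=samples)
    return mat, meta


def test_simple_de_null_false_positive_rate():
    rng = np.random.default_rng(11)
    mat, meta = _cohort_matrix(rng, n_feat=400)
    res = simple_de(mat, meta)
    assert (res.q_value < 0.05).mean() <= 0.05


def test_simple_de_power_on_injected_fold_change():
    """A 4-fold change at high counts reaches q < 0.05 in >= 90% of
    replicate cohorts of n = 8 + 8."""
    rng = np.random.default_rng(12)
    hits = 0
    reps = 100
    for _ in range(reps):
        mat, meta = _cohort_matrix(rng, n_feat=40, fold=4.0, hot=1)
        res = simple_de(mat, meta)
        hot_key = mat.counts.index[0]
        if res.loc[hot_key, "q_value"] < 0.05:
            hits += 1
    assert hits >= 90


def test_simple_de_excludes_all_zero_features():
    rng = np.random.default_rng(13)
    mat, meta = _cohort_matrix(rng, n_feat=30)
    mat.counts.iloc[5, :] = 0
    res = simple_de(mat, meta)
    dead = mat.counts.index[5]
    assert dead not in res.index
    assert dead in res.attrs["excluded_all_zero"]


# ---------------------------------------------------------------------------
# cell-type calls
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("expr,called", [
    ({"neuron": 0, "astro": 0, "oligo": 0, "micro": 0, "endo": 0}, []),
    ({"neuron": 100, "astro": 1, "oligo": 1, "micro": 1, "endo": 1},
     ["neuron"]),
    ({"neuron": 10, "astro": 10, "oligo": 10, "micro": 10, "endo": 10}, []),
])
def test_celltype_rule_arithmetic(expr, called):
    assert celltype_call(expr).called_types == called


def test_celltype_rule_variants_and_errors():
    expr = {"a": 50, "b": 2, "c": 4}
    loo = celltype_call(expr)
    assert loo.called_types == ["a"]  # mean(others)=3, sd~1.41
    # combined reading: threshold is 10 * (3 + 5 * 1.414) ~ 100.7
    assert celltype_call(expr, combined=True).called_types == []
    assert celltype_call({"a": 120, "b": 2, "c": 4},
                         combined=True).called_types == ["a"]
    with pytest.raises(ValueError):
        celltype_call({"a": -1, "b": 2})
    with pytest.raises(ValueError):
        celltype_call({"a": 5})
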