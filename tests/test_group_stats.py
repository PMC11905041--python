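"""Permutation, cluster, FDR, effect-size and correlation statistics.

Brute-force oracles (exhaustive enumeration, pair counting, hand step-up)
are implemented inline and the library results compared against them.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import restsync as rs
from restsync.stats import _relabelings

from scipy import stats as sps


# ---------------------------------------------------------------------------
# Summary t and Cohen's d
# ---------------------------------------------------------------------------

def test_pooled_t_demographics_row():
    t = rs.pooled_t_from_summary(23.54, 3.42, 28, 27.11, 1.89, 27)
    assert t == pytest.approx(-4.78, abs=0.03)


def test_pooled_t_equal_groups_zero():
    assert rs.pooled_t_from_summary(5.0, 1.2, 10, 5.0, 1.2, 10) == 0.0


def test_pooled_t_analytic_small_case():
    assert rs.pooled_t_from_summary(1, 1, 2, 0, 1, 2) == pytest.approx(1.0)


def test_pooled_t_degenerate_cases():
    assert rs.pooled_t_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5) == 0.0
    with pytest.raises(ValueError):
        rs.pooled_t_from_summary(3.0, 0.0, 5, 4.0, 0.0, 5)


def test_cohens_d_examples(rng):
    assert rs.cohens_d([2, 4], [1, 3]) == pytest.approx(1 / np.sqrt(2))
    x = rng.standard_normal(4000) + 1.0
    y = rng.standard_normal(4000)
    assert rs.cohens_d(x, y) == pytest.approx(1.0, abs=0.1)
    assert rs.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    with pytest.raises(ValueError):
        rs.cohens_d([1.0, 1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# Scalar permutation test vs exhaustive oracle
# ---------------------------------------------------------------------------

def _exhaustive_perm_p(a, b):
    """Brute-force two-sided permutation p over all C(n, n1) relabelings."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    t_obs = sps.ttest_ind(a, b, equal_var=True).statistic
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        t = sps.ttest_ind(pooled[sel], pooled[~sel], equal_var=True).statistic
        count += abs(t) >= abs(t_obs) - 1e-12
        total += 1
    return count / total


def test_exhaustive_separated_groups():
    p = rs.permutation_test([10, 11, 12], [0, 1, 2], n_perm=999, seed=0)
    assert p == pytest.approx(2 / 20)
    assert p == pytest.approx(_exhaustive_perm_p([10, 11, 12], [0, 1, 2]))


def test_exhaustive_identical_groups():
    assert rs.permutation_test([1, 2, 3], [1, 2, 3], n_perm=999, seed=0) == 1.0


def test_exhaustive_matches_oracle_random_data(rng):
    a = rng.standard_normal(4)
    b = rng.standard_normal(4) + 0.8
    p = rs.permutation_test(a, b, n_perm=10_000, seed=1)  # C(8,4)=70 -> exhaustive
    assert p == pytest.approx(_exhaustive_perm_p(a, b))


def test_degenerate_constant_values():
    assert rs.permutation_test([5.0, 5.0], [5.0, 5.0], n_perm=99, seed=0) == 1.0


def test_monotone_transform_invariance(rng):
    a = rng.uniform(1, 2, 4)
    b = rng.uniform(1.5, 2.5, 4)
    p_raw = rs.permutation_test(a, b, n_perm=10_000, seed=3)
    # rank-preserving transform applied identically to the pooled sample
    # changes the statistic but exchangeability-based extreme counts follow
    # the oracle either way
    assert p_raw == pytest.approx(_exhaustive_perm_p(a, b))
    p_tr = rs.permutation_test(np.exp(a), np.exp(b), n_perm=10_000, seed=3)
    assert p_tr == pytest.approx(_exhaustive_perm_p(np.exp(a), np.exp(b)))


def test_sampled_p_never_zero_and_seeded(rng):
    a = rng.standard_normal(15) + 3
    b = rng.standard_normal(15)
    p1 = rs.permutation_test(a, b, n_perm=499, seed=42)
    p2 = rs.permutation_test(a, b, n_perm=499, seed=42)
    assert p1 == p2
    assert p1 >= 1 / 500


# ---------------------------------------------------------------------------
# BH-FDR vs hand oracle
# ---------------------------------------------------------------------------

def _bh_oracle(pvals):
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def test_fdr_equal_pvalues_unchanged():
    adj, rej = rs.fdr_bh([0.05] * 10, q=0.05)
    np.testing.assert_allclose(adj, 0.05)
    assert rej.all()


def test_fdr_stepup_hand_case():
    adj, _ = rs.fdr_bh([0.005, 0.04, 0.04, 0.05])
    np.testing.assert_allclose(adj, [0.02, 0.05, 0.05, 0.05])
    np.testing.assert_allclose(adj, _bh_oracle([0.005, 0.04, 0.04, 0.05]))


def test_fdr_single_value_identity():
    adj, _ = rs.fdr_bh([0.03])
    assert adj[0] == pytest.approx(0.03)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st_.lists(st_.floats(0.001, 1.0), min_size=1, max_size=40))
def test_fdr_matches_oracle_and_dominates_bonferroni(pvals):
    adj, rej = rs.fdr_bh(pvals, q=0.05)
    np.testing.assert_allclose(adj, _bh_oracle(pvals), atol=1e-12)
    bonf = np.asarray(pvals) <= 0.05 / len(pvals)
    assert (rej | ~bonf).all()  # BH rejects a superset of Bonferroni


# ---------------------------------------------------------------------------
# Rank correlations vs pair-counting oracles
# ---------------------------------------------------------------------------

def _tau_b_oracle(x, y):
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))


def _rho_oracle(x, y):
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v)
        r = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def test_monotone_sequences_perfect_correlation():
    x = [1, 2, 3, 4, 5]
    assert rs.spearman_rho(x, [2, 4, 8, 16, 32]) == pytest.approx(1.0)
    assert rs.kendall_tau_b(x, [2, 4, 8, 16, 32]) == pytest.approx(1.0)
    assert rs.spearman_rho(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)
    assert rs.kendall_tau_b(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)


def test_rank_correlations_hand_case():
    x, y = [1, 2, 3, 4], [1, 3, 2, 4]
    assert rs.kendall_tau_b(x, y) == pytest.approx(4 / 6)
    assert rs.spearman_rho(x, y) == pytest.approx(0.8)


def test_rank_correlations_with_ties_match_oracles(rng):
    for _ in range(5):
        x = rng.integers(0, 5, 12).astype(float)
        y = rng.integers(0, 5, 12).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        assert rs.kendall_tau_b(x, y) == pytest.approx(_tau_b_oracle(x, y), abs=1e-12)
        assert rs.spearman_rho(x, y) == pytest.approx(_rho_oracle(x, y), abs=1e-12)


def test_zero_rank_variance_is_error():
    with pytest.raises(ValueError):
        rs.spearman_rho([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# IQR outliers
# ---------------------------------------------------------------------------

def test_iqr_flags_extreme_value():
    values = np.r_[np.arange(1, 10), 100.0]
    q1, q3 = np.percentile(values, [25, 75])
    assert q3 + 1.5 * (q3 - q1) < 100.0  # oracle fence
    mask = rs.iqr_outliers(values)
    assert mask.sum() == 1 and mask[-1]


def test_iqr_constant_and_symmetric_clean():
    assert not rs.iqr_outliers(np.full(6, 2.0)).any()
    assert not rs.iqr_outliers(np.arange(1, 11, dtype=float)).any()


# ---------------------------------------------------------------------------
# Edge-wise test
# ---------------------------------------------------------------------------

def _edge_matrix(values_by_edge, labels):
    n = len(labels)
    v = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    v[iu] = values_by_edge
    v = v + v.T
    return rs.ConnectivityMatrix(values=np.clip(v, 0, 1), metric="ciplv",
                                 band=("theta", 4.0, 9.0), labels=labels)


def test_single_edge_reduces_to_permutation_test(rng):
    labels = ["a", "b"]
    vals_a = rng.uniform(0.4, 0.6, 3)
    vals_b = rng.uniform(0.1, 0.3, 3)
    mats_a = [_edge_matrix([v], labels) for v in vals_a]
    mats_b = [_edge_matrix([v], labels) for v in vals_b]
    res = rs.edgewise_group_test(mats_a, mats_b, n_perm=999, seed=7)
    p_scalar = rs.permutation_test(vals_a, vals_b, n_perm=999, seed=7)
    assert res.table["p"].iloc[0] == pytest.approx(p_scalar)


def test_edgewise_band_mismatch_is_error(rng):
    a = _edge_matrix([0.5], ["a", "b"])
    b = rs.ConnectivityMatrix(values=np.zeros((2, 2)), metric="ciplv",
                              band=("alpha", 9.0, 14.0), labels=["a", "b"])
    with pytest.raises(ValueError, match="band"):
        rs.edgewise_group_test([a, a], [b, b], n_perm=99, seed=0)


def test_edgewise_planted_edge_detected(rng):
    labels = [f"c{i}" for i in range(6)]
    n_edges = 15
    mats_a, mats_b = [], []
    for _ in range(14):
        base = rng.uniform(0.2, 0.3, n_edges)
        boosted = base.copy()
        boosted[0] += 0.3
        mats_a.append(_edge_matrix(boosted + rng.normal(0, 0.02, n_edges), labels))
        mats_b.append(_edge_matrix(base + rng.normal(0, 0.02, n_edges), labels))
    res = rs.edgewise_group_test(mats_a[:14], mats_b[:14], n_perm=1999, seed=1)
    tab = res.table
    assert tab["p_fdr"].iloc[0] < 0.05
    assert tab["direction"].iloc[0] == "A>B"
    assert tab["p_fdr"].iloc[1:].min() > 0.2


# ---------------------------------------------------------------------------
# Cluster permutation test
# ---------------------------------------------------------------------------

def _bfs_components(nodes, edges):
    """Oracle: connected components by breadth-first search."""
    nodes = set(int(n) for n in nodes)
    adj = {n: set() for n in nodes}
    for i, j in edges:
        if i in nodes and j in nodes:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for start in sorted(nodes):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def test_cluster_members_match_bfs_oracle(montage, adjacency, rng):
    n1, n2 = 14, 14
    maps_a = rng.standard_normal((n1, 64))
    maps_b = rng.standard_normal((n2, 64))
    # plant a strong centroparietal offset
    for lab in ("CPz", "Pz", "P2", "CP1", "CP2", "Cz"):
        maps_a[:, montage.index(lab)] += 2.0
    res = rs.cluster_permutation_test(maps_a, maps_b, adjacency, n_perm=499, seed=2)
    pos = set(np.flatnonzero(res.t_obs > res.threshold))
    neg = set(np.flatnonzero(res.t_obs < -res.threshold))
    oracle = _bfs_components(pos, adjacency.edges) | _bfs_components(neg, adjacency.edges)
    got = {frozenset(c["members"]) for c in res.clusters}
    assert got == oracle


def test_cluster_with_planted_effect_contains_pz(montage, adjacency, rng):
    maps_a = rng.standard_normal((20, 64)) * 0.5
    maps_b = rng.standard_normal((20, 64)) * 0.5
    for lab in ("CPz", "Pz", "P2", "CP1", "CP2"):
        maps_a[:, montage.index(lab)] += 1.0
    res = rs.cluster_permutation_test(maps_a, maps_b, adjacency, n_perm=999, seed=5)
    sig = [c for c in res.clusters if c["p"] < 0.05]
    assert sig, "expected a significant cluster"
    assert any(montage.index("Pz") in c["members"] for c in sig)
    assert all(c["sign"] == 1 for c in sig)


def test_isolated_suprathreshold_electrode_is_singleton_cluster(rng):
    # a three-node path graph a-b-c; only node 0 carries any group
    # difference (the other columns are identical across groups, t = 0)
    adjacency = rs.AdjacencyGraph(n_nodes=3, edges={(0, 1), (1, 2)})
    shared = rng.standard_normal((10, 3)) * 0.1
    maps_a = shared.copy()
    maps_b = shared.copy()
    maps_a[:, 0] += 2.0 + rng.standard_normal(10) * 0.1
    res = rs.cluster_permutation_test(maps_a, maps_b, adjacency, n_perm=199, seed=0)
    biggest = max(res.clusters, key=lambda c: c["mass"])
    assert biggest["members"] == [0]


def test_cluster_seeded_determinism(adjacency, rng):
    maps_a = rng.standard_normal((10, 64))
    maps_b = rng.standard_normal((10, 64))
    r1 = rs.cluster_permutation_test(maps_a, maps_b, adjacency, n_perm=299, seed=9)
    r2 = rs.cluster_permutation_test(maps_a, maps_b, adjacency, n_perm=299, seed=9)
    assert [c["p"] for c in r1.clusters] == [c["p"] for c in r2.clusters]
    assert [c["members"] for c in r1.clusters] == [c["members"] for c in r2.clusters]


def test_relabelings_exhaustive_when_feasible(rng):
    labels, exhaustive = _relabelings(6, 3, 1000, rng)
    assert exhaustive
    assert labels.shape == (20, 6)
    assert (labels.sum(axis=1) == 3).all()
    # distinct relabelings
    assert len({tuple(row) for row in labels}) == 20
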