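"""Between-group and association statistics.

Permutation machinery (scalar, edge-wise with a shared schedule, and
cluster-based with a max-statistic null) is implemented here; ordinary
textbook statistics (rank correlations, BH-FDR) delegate to scipy /
statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .data_model import AdjacencyGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Two-sample pooled-variance t statistic from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    sp_sq = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp_sq == 0:
        if m1 == m2:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return (m1 - m2) / np.sqrt(sp_sq * (1 / n1 + 1 / n2))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD standardised mean difference (sign preserved)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp_sq = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if sp_sq == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(sp_sq))


def iqr_outliers(values: np.ndarray) -> np.ndarray:
    """Tukey fences: flag values beyond 1.5 IQR outside [Q1, Q3]."""
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("IQR outlier detection needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank-order correlation (average ranks for ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance")
    return float(sps.spearmanr(x, y).statistic)


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b (tie-corrected)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance")
    return float(sps.kendalltau(x, y, variant="b").statistic)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, reject


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _pooled_t_columns(
    x: np.ndarray, group_a: np.ndarray, n1: int, dtype=np.float64
) -> np.ndarray:
    """Pooled t per column of ``x`` for one or many relabelings.

    ``x`` is (n_subjects, n_features); ``group_a`` is a boolean matrix
    (n_relabelings, n_subjects).  Returns (n_relabelings, n_features).
    Features with zero pooled variance get t = 0.  Large sampled nulls can
    be computed in float32 (``dtype``): permutation counts only compare
    magnitudes, so single precision is ample there.
    """
    n = x.shape[0]
    n2 = n - n1
    x = x.astype(dtype, copy=False)
    ga = group_a.astype(dtype)
    s1 = ga @ x
    q1 = ga @ (x * x)
    st = x.sum(axis=0)
    qt = (x * x).sum(axis=0)
    m1 = s1 / n1
    m2 = (st - s1) / n2
    sp_sq = (q1 - n1 * m1 * m1 + (qt - q1) - n2 * m2 * m2) / (n - 2)
    np.clip(sp_sq, 0, None, out=sp_sq)
    denom = np.sqrt(sp_sq * dtype(1 / n1 + 1 / n2))
    zero = denom == 0
    denom[zero] = 1.0
    t = (m1 - m2) / denom
    t[zero] = 0.0
    return t


def _relabelings(
    n: int, n1: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean group-A indicator matrix over relabelings.

    If the number of distinct relabelings is at most ``n_perm`` the full
    enumeration is returned (exhaustive=True, identity included); otherwise
    ``n_perm`` uniform random relabelings.
    """
    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        out = np.zeros((n_distinct, n), dtype=bool)
        for r, idx in enumerate(combinations(range(n), n1)):
            out[r, list(idx)] = True
        return out, True
    out = np.zeros((n_perm, n), dtype=bool)
    for r in range(n_perm):
        out[r, rng.permutation(n)[:n1]] = True
    return out, False


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 50_000,
    seed: int | None = None,
    two_sided: bool = True,
) -> float:
    """Two-sample permutation p-value with the pooled t as test statistic.

    Sampled nulls use the add-one convention p = (1 + #extreme)/(1 + n_perm);
    when all C(n, n1) relabelings fit within ``n_perm`` the null is
    enumerated exhaustively and p = #extreme / #relabelings (the identity
    relabeling is part of the enumeration, so p > 0 always).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.concatenate([a, b])[:, None]
    if np.ptp(x) == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = _pooled_t_columns(x, np.arange(x.size)[None, :] < a.size, a.size)[0, 0]
    labels, exhaustive = _relabelings(x.shape[0], a.size, n_perm, rng)
    t_null = _pooled_t_columns(x, labels, a.size)[:, 0]
    if two_sided:
        extreme = np.abs(t_null) >= np.abs(obs) - 1e-12
    else:
        extreme = t_null >= obs - 1e-12
    if exhaustive:
        return float(extreme.sum() / labels.shape[0])
    return float((1 + extreme.sum()) / (1 + labels.shape[0]))


@dataclass
class EdgeStatResult:
    """Edge-wise group comparison over one band's connectivity matrices."""

    table: pd.DataFrame  # columns: edge, channel_i, channel_j, t, d, p, p_fdr, direction
    band: tuple[str, float, float]
    n_perm: int
    seed: int | None
    exhaustive: bool


def edgewise_group_test(
    mats_a: list,
    mats_b: list,
    n_perm: int = 50_000,
    seed: int | None = None,
    q: float = 0.05,
) -> EdgeStatResult:
    """Permutation test per unordered edge with a shared permutation schedule,
    BH-FDR corrected across edges within the band.

    The same relabelings are applied to every edge, preserving the spatial
    correlation structure of the null.
    """
    if len(mats_a) < 2 or len(mats_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    band = mats_a[0].band
    labels = mats_a[0].labels
    for m in mats_a + mats_b:
        if m.band != band or m.labels != labels:
            raise ValueError("all matrices must share band and montage")
    n_ch = len(labels)
    iu = np.triu_indices(n_ch, k=1)
    x = np.stack([m.values[iu] for m in mats_a] + [m.values[iu] for m in mats_b])
    n1 = len(mats_a)
    rng = np.random.default_rng(seed)
    obs = _pooled_t_columns(x, np.arange(x.shape[0])[None, :] < n1, n1)[0]
    relab, exhaustive = _relabelings(x.shape[0], n1, n_perm, rng)
    null_dtype = np.float32 if relab.shape[0] * x.shape[1] > 1_000_000 else np.float64
    t_null = _pooled_t_columns(x, relab, n1, dtype=null_dtype)
    tol = 1e-6 if null_dtype is np.float32 else 1e-12
    extreme_counts = (np.abs(t_null) >= (np.abs(obs) * (1 - tol))[None, :]).sum(axis=0)
    if exhaustive:
        pvals = extreme_counts / relab.shape[0]
    else:
        pvals = (1 + extreme_counts) / (1 + relab.shape[0])
    adjusted, _ = fdr_bh(pvals, q=q)
    # vectorised pooled-SD Cohen's d per edge (0 where the pooled SD is 0)
    n2 = x.shape[0] - n1
    va = x[:n1].var(axis=0, ddof=1)
    vb = x[n1:].var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp > 0, (x[:n1].mean(axis=0) - x[n1:].mean(axis=0)) / np.where(sp > 0, sp, 1.0), 0.0)
    table = pd.DataFrame(
        {
            "channel_i": [labels[i] for i in iu[0]],
            "channel_j": [labels[j] for j in iu[1]],
            "t": obs,
            "d": d,
            "p": pvals,
            "p_fdr": adjusted,
            "direction": np.where(obs >= 0, "A>B", "B>A"),
        }
    )
    return EdgeStatResult(table=table, band=band, n_perm=n_perm, seed=seed,
                          exhaustive=exhaustive)


@dataclass
class ClusterResult:
    """Cluster-based permutation test outcome on electrode maps."""

    clusters: list[dict]  # {"members": [idx], "mass": float, "p": float, "sign": +-1}
    t_obs: np.ndarray
    threshold: float
    n_perm: int
    seed: int | None
    cluster_alpha: float = 0.05


def _cluster_masses(
    t_vals: np.ndarray, mask: np.ndarray, adj
) -> list[tuple[np.ndarray, float]]:
    """Sign-consistent connected components of supra-threshold electrodes.

    Positive and negative candidate electrodes form clusters separately
    (adjacent supra-threshold electrodes of opposite sign belong to
    different clusters); mass is the summed |t| of the members.
    """
    out = []
    for sign_mask in (mask & (t_vals > 0), mask & (t_vals < 0)):
        nodes = np.flatnonzero(sign_mask)
        if nodes.size == 0:
            continue
        sub = adj[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = nodes[labels == c]
            out.append((members, float(np.abs(t_vals[members]).sum())))
    return out


def cluster_permutation_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    adjacency: AdjacencyGraph,
    n_perm: int = 50_000,
    seed: int | None = None,
    cluster_alpha: float = 0.05,
) -> ClusterResult:
    """Cluster-mass permutation test on per-subject electrode maps.

    Electrode-wise pooled t values exceeding the two-sided t threshold at
    ``cluster_alpha`` form candidate nodes; connected components under the
    montage adjacency are clusters scored by summed |t|; each observed
    cluster's p-value compares its mass against the permutation null of the
    maximum cluster mass (positive and negative clusters pooled, matching
    the two-sided electrode threshold).
    """
    maps_a = np.asarray(maps_a, float)
    maps_b = np.asarray(maps_b, float)
    if maps_a.ndim != 2 or maps_b.ndim != 2 or maps_a.shape[1] != maps_b.shape[1]:
        raise ValueError("maps must be (n_subjects, n_electrodes) with equal widths")
    if maps_a.shape[1] != adjacency.n_nodes:
        raise ValueError("adjacency does not match electrode count")
    if not adjacency.is_connected():
        logger.warning("adjacency is disconnected; clusters cannot span components")
    n1, n2 = maps_a.shape[0], maps_b.shape[0]
    x = np.vstack([maps_a, maps_b])
    rng = np.random.default_rng(seed)
    df = n1 + n2 - 2
    threshold = float(sps.t.ppf(1 - cluster_alpha / 2, df))
    adj = adjacency.to_sparse()

    t_obs = _pooled_t_columns(x, np.arange(n1 + n2)[None, :] < n1, n1)[0]
    observed = _cluster_masses(t_obs, np.abs(t_obs) > threshold, adj)

    relab, exhaustive = _relabelings(n1 + n2, n1, n_perm, rng)
    t_null = _pooled_t_columns(x, relab, n1)
    null_max = np.zeros(relab.shape[0])
    supra = np.abs(t_null) > threshold
    for r in np.flatnonzero(supra.any(axis=1)):
        masses = _cluster_masses(t_null[r], supra[r], adj)
        null_max[r] = max(m for _, m in masses)

    clusters = []
    denom = relab.shape[0] if exhaustive else 1 + relab.shape[0]
    for members, mass in observed:
        count = int((null_max >= mass - 1e-12).sum())
        p = count / denom if exhaustive else (1 + count) / denom
        clusters.append(
            {
                "members": [int(i) for i in members],
                "mass": mass,
                "p": float(min(p, 1.0)),
                "sign": int(np.sign(t_obs[members[0]])),
            }
        )
    clusters.sort(key=lambda c: c["p"])
    return ClusterResult(
        clusters=clusters, t_obs=t_obs, threshold=threshold,
        n_perm=n_perm, seed=seed, cluster_alpha=cluster_alpha,
    )
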