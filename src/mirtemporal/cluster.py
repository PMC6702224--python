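"""Clustering of temporal profiles and concordance between clusterings.

Two elastic/rigid notions of profile similarity are supported: correlation
distance (1 - Pearson r across the age-ordered samples) and dynamic time
warping (DTW) distance.  Profiles are grouped by hierarchical clustering
with the Ward-2 criterion applied to either distance, and the number of
clusters is chosen with the gap statistic.

Agreement between two clusterings is summarised as a weighted bipartite
graph (edge weight = number of shared features between a left and a right
cluster), ordered by an iterated barycenter heuristic to minimise edge
crossings.  The Index of Agreement (IoA) is the ratio of the number of
edges crossing no other edge to the number of edges crossing at least one
(clamped denominator), and its null distribution comes from re-clustering
age-permuted profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .temporal import TemporalProfileSet

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "ConcordanceResult",
    "GapResult",
    "correlation_distance",
    "dtw_distance",
    "dtw_pair",
    "hierarchical_clusters",
    "gap_statistic",
    "bipartite_concordance",
    "ioa_permutation_test",
]

METRICS = ("one_minus_pearson", "dtw")


def _as_matrix(profiles) -> tuple[np.ndarray, list[str]]:
    if isinstance(profiles, TemporalProfileSet):
        return np.asarray(profiles.zscores, dtype=float), list(profiles.feature_ids)
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2:
        raise ValueError("profiles must be a 2-D features x samples array")
    return arr, [str(i) for i in range(arr.shape[0])]


@dataclass
class DistanceMatrix:
    feature_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.feature_ids):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.feature_ids)


@dataclass
class ClusterAssignment:
    """feature_id -> group label in 1..k."""

    feature_ids: list[str]
    labels: np.ndarray
    k: int
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.feature_ids):
            raise ValueError("labels must align with feature_ids")
        present = set(self.labels.tolist())
        if not present <= set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")
        if present != set(range(1, self.k + 1)):
            raise ValueError("empty cluster in assignment")

    def members(self, label: int) -> list[str]:
        return [f for f, l in zip(self.feature_ids, self.labels) if l == label]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.feature_ids, self.labels.tolist()))


def correlation_distance(profiles) -> DistanceMatrix:
    """1 - Pearson r between feature rows; zero-variance rows are excluded
    with a warning."""
    x, ids = _as_matrix(profiles)
    if x.shape[1] < 3:
        raise ValueError("correlation distance needs >= 3 samples")
    sd = x.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} zero-variance features from distances")
        x, ids = x[keep], [f for f, k in zip(ids, keep) if k]
    r = np.corrcoef(x)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, (d + d.T) / 2.0, "one_minus_pearson")


@njit(cache=True)
def _dtw_single(x, y, diag_weight, band):  # pragma: no cover - numba
    n, m = len(x), len(y)
    INF = 1e300
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band >= 0:
            c = int(round(i * m / n))
            jlo = max(1, c - band)
            jhi = min(m, c + band)
        for j in range(jlo, jhi + 1):
            c = abs(x[i - 1] - y[j - 1])
            if i == 1 and j == 1:
                D[1, 1] = c  # first matched cell always counted once
                continue
            best = D[i - 1, j - 1] + diag_weight * c
            if D[i - 1, j] + c < best:
                best = D[i - 1, j] + c
            if D[i, j - 1] + c < best:
                best = D[i, j - 1] + c
            D[i, j] = best
    return D[n, m]


@njit(cache=True)
def _dtw_pairwise(x, diag_weight, band):  # pragma: no cover - numba
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_single(x[i], x[j], diag_weight, band)
            out[i, j] = d
            out[j, i] = d
    return out


def dtw_pair(x, y, step: str = "symmetric1", window: int | None = None) -> float:
    """DTW alignment cost between two equal-grid series with |a - b| local
    cost.  ``step="symmetric1"`` is the plain path-sum recursion (all steps
    weight 1); ``"symmetric2"`` doubles the diagonal step.  ``window`` is an
    optional Sakoe-Chiba band half-width."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("series length must be >= 2")
    weight = {"symmetric1": 1.0, "symmetric2": 2.0}.get(step)
    if weight is None:
        raise ValueError(f"unknown step pattern {step!r}")
    return float(_dtw_single(x, y, weight, -1 if window is None else int(window)))


def dtw_distance(
    profiles, step: str = "symmetric1", window: int | None = None
) -> DistanceMatrix:
    """Pairwise DTW distances between all feature profiles (shared sample
    grid)."""
    x, ids = _as_matrix(profiles)
    if x.shape[1] < 2:
        raise ValueError("series length must be >= 2")
    weight = {"symmetric1": 1.0, "symmetric2": 2.0}.get(step)
    if weight is None:
        raise ValueError(f"unknown step pattern {step!r}")
    d = _dtw_pairwise(np.ascontiguousarray(x), weight, -1 if window is None else int(window))
    return DistanceMatrix(ids, d, "dtw")


def hierarchical_clusters(
    dist: DistanceMatrix, k: int, linkage: str = "ward.D2"
) -> ClusterAssignment:
    """Agglomerative clustering on a precomputed distance matrix, cut to k.

    ``ward.D2`` applies the Ward-2 Lance-Williams update directly to the
    provided distances (for DTW distances this is an approximation, since
    they are not Euclidean).  Labels are renumbered 1..k in order of first
    appearance, so the output is deterministic; ties in merge height follow
    the nearest-neighbor-chain order of the linkage algorithm.
    """
    if not 1 <= k <= dist.n:
        raise ValueError(f"k={k} outside 1..{dist.n}")
    method = {"ward.D2": "ward", "average": "average", "complete": "complete"}.get(linkage)
    if method is None:
        raise ValueError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(squareform(dist.values, checks=False), method=method)
    raw = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, l in enumerate(raw):
        if l not in relabel:
            relabel[l] = len(relabel) + 1
        labels[i] = relabel[l]
    return ClusterAssignment(dist.feature_ids, labels, k, method=f"{linkage}/{dist.metric}")


def _metric_distance(x: np.ndarray, metric: str, window: int | None = None) -> DistanceMatrix:
    if metric == "one_minus_pearson":
        return correlation_distance(x)
    if metric == "dtw":
        return dtw_distance(x, window=window)
    raise ValueError(f"unknown metric {metric!r}")


def _pooled_within_dispersion(dist: DistanceMatrix, labels: np.ndarray) -> float:
    """W_k = sum_r (1 / 2 n_r) * sum_{i,j in r} d_ij^2."""
    w = 0.0
    d2 = dist.values**2
    for l in np.unique(labels):
        idx = np.flatnonzero(labels == l)
        if len(idx) > 1:
            w += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return w


@dataclass
class GapResult:
    k_selected: int
    ks: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    log_w: np.ndarray
    log_w_ref_mean: np.ndarray
    rule_satisfied: bool = True


def gap_statistic(
    profiles,
    k_max: int,
    B: int = 50,
    seed: int | None = None,
    metric: str = "one_minus_pearson",
    linkage: str = "ward.D2",
    reference: str = "svd",
) -> GapResult:
    """Gap-statistic selection of the cluster number.

    Gap(k) = E*[log W_k] - log W_k, with the reference expectation over B
    null datasets.  ``reference="svd"`` (default) draws uniformly within
    the box spanned by the data in its principal-axis frame, so the null
    shares the profiles' low effective dimensionality (smoothed
    trajectories occupy a thin subspace of sample space, and an axis-
    aligned uniform box badly overstates their null dispersion);
    ``reference="uniform"`` is the plain per-sample-range box.  The
    selected k is the smallest with Gap(k) >= Gap(k+1) - s_{k+1}
    (one-standard-error rule); if no k satisfies it, k_max is returned
    with ``rule_satisfied=False``.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10")
    x, _ = _as_matrix(profiles)
    if np.allclose(x, x[0:1, :]):
        raise ValueError("degenerate data: all profiles identical")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)

    def log_w_curve(data: np.ndarray) -> np.ndarray:
        dist = _metric_distance(data, metric)
        method = {"ward.D2": "ward", "average": "average", "complete": "complete"}[linkage]
        Z = hierarchy.linkage(squareform(dist.values, checks=False), method=method)
        cuts = hierarchy.cut_tree(Z, n_clusters=ks.tolist())
        return np.array(
            [np.log(max(_pooled_within_dispersion(dist, cuts[:, i]), 1e-300)) for i in range(len(ks))]
        )

    log_w = log_w_curve(x)
    if reference == "svd":
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        z0 = xc @ vt.T
        lo, hi = z0.min(axis=0), z0.max(axis=0)

        def draw() -> np.ndarray:
            return rng.uniform(lo, hi, size=z0.shape) @ vt + mu

    elif reference == "uniform":
        lo = x.min(axis=0, keepdims=True)
        hi = x.max(axis=0, keepdims=True)

        def draw() -> np.ndarray:
            return rng.uniform(lo, hi, size=x.shape)

    else:
        raise ValueError(f"unknown reference {reference!r}")
    ref = np.empty((B, len(ks)))
    for b in range(B):
        ref[b] = log_w_curve(draw())
    ref_mean = ref.mean(axis=0)
    s_k = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    gap = ref_mean - log_w

    k_selected, satisfied = k_max, False
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            k_selected, satisfied = int(ks[i]), True
            break
    return GapResult(k_selected, ks, gap, s_k, log_w, ref_mean, satisfied)


# ---------------------------------------------------------------------------
# bipartite concordance


@dataclass
class ConcordanceResult:
    edges: list[tuple[int, int, int]]  # (left label, right label, weight)
    left_order: list[int]
    right_order: list[int]
    n_noncrossing: int
    n_crossing: int
    index_of_agreement: float
    p_value: float | None = None
    null_ioa: np.ndarray | None = field(default=None, repr=False)

    def to_dot(self) -> str:
        """Graphviz DOT export of the weighted bipartite graph (node ranks
        follow the barycenter orders)."""
        lines = ["graph concordance {", "  rankdir=LR;"]
        for l in self.left_order:
            lines.append(f'  "L{l}" [label="A{l}"];')
        for r in self.right_order:
            lines.append(f'  "R{r}" [label="B{r}"];')
        for l, r, w in self.edges:
            lines.append(f'  "L{l}" -- "R{r}" [penwidth={w}, label="{w}"];')
        lines.append("}")
        return "\n".join(lines)


def _barycenter_orders(
    edges: list[tuple[int, int, int]],
    left_labels: list[int],
    right_labels: list[int],
    n_iter: int = 8,
) -> tuple[list[int], list[int]]:
    """Iterated weighted-barycenter ordering of the two node layers; ties
    break by node label."""
    left_order = sorted(left_labels)
    right_order = sorted(right_labels)
    for _ in range(n_iter):
        lpos = {l: i for i, l in enumerate(left_order)}
        bary = {}
        for r in right_order:
            ws = [(w, lpos[l]) for l, rr, w in edges if rr == r]
            bary[r] = sum(w * p for w, p in ws) / sum(w for w, _ in ws) if ws else 0.0
        new_right = sorted(right_order, key=lambda r: (bary[r], r))
        rpos = {r: i for i, r in enumerate(new_right)}
        bary_l = {}
        for l in left_order:
            ws = [(w, rpos[rr]) for ll, rr, w in edges if ll == l]
            bary_l[l] = sum(w * p for w, p in ws) / sum(w for w, _ in ws) if ws else 0.0
        new_left = sorted(left_order, key=lambda l: (bary_l[l], l))
        if new_left == left_order and new_right == right_order:
            break
        left_order, right_order = new_left, new_right
    return left_order, right_order


def _count_crossing_edges(
    edges: list[tuple[int, int, int]],
    left_order: list[int],
    right_order: list[int],
) -> tuple[int, int]:
    """Edge-level counts: an edge is 'crossing' if it crosses at least one
    other edge; two edges (i,j),(k,l) cross iff
    (pos(i)-pos(k)) * (pos(j)-pos(l)) < 0."""
    lpos = {l: i for i, l in enumerate(left_order)}
    rpos = {r: i for i, r in enumerate(right_order)}
    crossing = [False] * len(edges)
    for a in range(len(edges)):
        la, ra, _ = edges[a]
        for b in range(a + 1, len(edges)):
            lb, rb, _ = edges[b]
            if (lpos[la] - lpos[lb]) * (rpos[ra] - rpos[rb]) < 0:
                crossing[a] = crossing[b] = True
    n_cross = sum(crossing)
    return len(edges) - n_cross, n_cross


def bipartite_concordance(a: ClusterAssignment, b: ClusterAssignment) -> ConcordanceResult:
    """Weighted bipartite comparison of two clusterings of the same
    features; IoA = n_noncrossing / max(n_crossing, 1)."""
    if set(a.feature_ids) != set(b.feature_ids):
        raise ValueError("clusterings cover different feature sets")
    b_map = b.as_dict()
    weights: dict[tuple[int, int], int] = {}
    for f, la in zip(a.feature_ids, a.labels):
        key = (int(la), int(b_map[f]))
        weights[key] = weights.get(key, 0) + 1
    edges = [(l, r, w) for (l, r), w in sorted(weights.items())]
    left_labels = sorted({l for l, _, _ in edges})
    right_labels = sorted({r for _, r, _ in edges})
    left_order, right_order = _barycenter_orders(edges, left_labels, right_labels)
    n_non, n_cross = _count_crossing_edges(edges, left_order, right_order)
    ioa = n_non / max(n_cross, 1)
    return ConcordanceResult(edges, left_order, right_order, n_non, n_cross, ioa)


def ioa_permutation_test(
    profiles,
    k_a: int,
    k_b: int,
    method_a: str = "one_minus_pearson",
    method_b: str = "dtw",
    n_perm: int = 5000,
    seed: int | None = None,
    window: int | None = None,
    reselect_k: bool = False,
    gap_kwargs: dict | None = None,
) -> ConcordanceResult:
    """Permutation test of clustering concordance.

    The observed IoA compares the method-a and method-b clusterings of the
    profiles.  The null reorders each feature's values independently across
    the age-ordered samples, re-clusters the permuted data with method b
    and scores IoA against the *fixed* method-a clustering;
    p = (1 + #{null >= observed}) / (n_perm + 1).  By default k_b is reused
    for the permuted data (cheap); ``reselect_k=True`` re-runs the gap
    statistic per permutation (``gap_kwargs`` forwarded, B cost per
    permutation).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, ids = _as_matrix(profiles)
    rng = np.random.default_rng(seed)
    dist_a = _metric_distance(x, method_a, window)
    dist_b = _metric_distance(x, method_b, window)
    ca = hierarchical_clusters(dist_a, k_a)
    cb = hierarchical_clusters(dist_b, k_b)
    observed = bipartite_concordance(ca, cb)

    null = np.empty(n_perm)
    for p in range(n_perm):
        xp = rng.permuted(x, axis=1)
        dist_p = _metric_distance(xp, method_b, window)
        kp = k_b
        if reselect_k:
            kw = {"k_max": max(k_b, 2), "B": 10, "metric": method_b}
            kw.update(gap_kwargs or {})
            kp = gap_statistic(
                xp, seed=int(rng.integers(2**31 - 1)), **kw
            ).k_selected
        cp = hierarchical_clusters(dist_p, kp)
        cp = ClusterAssignment(ids, cp.labels, cp.k, cp.method)
        null[p] = bipartite_concordance(ca, cp).index_of_agreement
    p_value = (1.0 + np.sum(null >= observed.index_of_agreement)) / (n_perm + 1.0)
    observed.p_value = float(p_value)
    observed.null_ioa = null
    return observed
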