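"""Missing-aware distances, PAM, silhouette widths and Ward agglomeration.

All routines operate on a precomputed :class:`DistanceMatrix` so that the
missing-genotype scaling rule is applied once: when two samples share only
``m_ij`` of ``m`` markers, the squared distance over the shared markers is
scaled up by ``m / m_ij`` (the distance is scaled up proportionally to the
number of markers actually used).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "Partition",
    "PAMResult",
    "Dendrogram",
    "SilhouetteResult",
    "pairwise_distance",
    "pam",
    "silhouette",
    "pamk_select",
    "ward_linkage",
    "pct_change_heights",
    "select_k_heights",
    "cut_tree",
]


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric: str  # "euclidean" | "squared_euclidean"
    overlap: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Partition:
    labels: np.ndarray  # 1..k
    k: int
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError("labels must use 1..k with every cluster non-empty")


@dataclass
class PAMResult:
    partition: Partition
    medoids: np.ndarray
    objective: float
    avg_silhouette: float | None = None
    silhouette_trace: dict = field(default_factory=dict)


@dataclass
class Dendrogram:
    """Agglomeration history: row t merges clusters ``child_a``/``child_b``
    at ``height`` into new cluster id ``n + t`` of the given ``size``.
    Original samples are clusters ``0..n-1``."""

    n: int
    child_a: np.ndarray
    child_b: np.ndarray
    heights: np.ndarray
    sizes: np.ndarray


@dataclass
class SilhouetteResult:
    a: np.ndarray
    b: np.ndarray
    widths: np.ndarray
    average: float


def pairwise_distance(X: np.ndarray, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances over shared observed markers, scaled for missingness.

    d2_ij = (m / m_ij) * sum over markers observed in both rows of (x_i - x_j)^2
    with m_ij the shared-observed count; ``euclidean`` reports sqrt(d2),
    ``squared_euclidean`` reports d2.
    """
    if metric not in ("euclidean", "squared_euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    obs = (~np.isnan(X)).astype(float)
    Z = np.nan_to_num(X)
    Z2 = Z * Z
    # sum over shared markers of (x_i - x_j)^2, assembled from masked pieces
    sq = Z2 @ obs.T + obs @ Z2.T - 2.0 * (Z @ Z.T)
    overlap = obs @ obs.T
    np.fill_diagonal(overlap, np.maximum(np.diag(overlap), 1.0))
    if np.any(overlap < 1):
        pairs = np.argwhere((overlap < 1) & ~np.eye(n, dtype=bool))
        pairs = [tuple(p) for p in pairs if p[0] < p[1]]
        raise ValueError(f"sample pairs share no observed markers: {pairs}")
    d2 = (m / overlap) * sq
    d2 = np.maximum(d2, 0.0)  # clip tiny negative round-off
    np.fill_diagonal(d2, 0.0)
    d2 = 0.5 * (d2 + d2.T)
    values = np.sqrt(d2) if metric == "euclidean" else d2
    return DistanceMatrix(values=values, metric=metric, overlap=overlap.astype(int))


def _assign_to_medoids(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid index (position within ``medoids``); ties -> lowest."""
    return np.argmin(D[:, medoids], axis=1)


def _swap_phase(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-improvement SWAP: repeatedly apply the single medoid/non-medoid
    exchange that most reduces the objective, until none improves."""
    n = d.shape[0]
    k = len(medoids)
    medoids = np.array(sorted(medoids))
    objective = _objective(d, medoids)
    while True:
        order = np.argsort(d[:, medoids], axis=1)
        d1 = d[np.arange(n), medoids[order[:, 0]]]
        d2 = (d[np.arange(n), medoids[order[:, 1]]] if k > 1
              else np.full(n, np.inf))
        nearest_medoid = medoids[order[:, 0]]

        best = (0.0, None, None)
        for mi, mval in enumerate(medoids):
            lost = nearest_medoid == mval
            # cost of each candidate replacement h (columns of d)
            repl = np.where(lost[:, None], np.minimum(d2[:, None], d),
                            np.minimum(d1[:, None], d))
            totals = repl.sum(axis=0)
            totals[medoids] = np.inf
            h = int(np.argmin(totals))
            delta = totals[h] - objective
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            return medoids, objective
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
        medoids = np.array(sorted(medoids))
        objective = _objective(d, medoids)


def pam(D: DistanceMatrix, k: int, seed: int | None = None,
        n_restarts: int = 0) -> PAMResult:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    Deterministic given the distance matrix (ties in BUILD selection and in
    SWAP gains go to the lowest index).  SWAP reaches a 1-exchange local
    optimum; ``n_restarts`` additional SWAP runs from seeded random medoid
    sets help escape such optima on hard instances, keeping the best
    objective (still deterministic given ``seed``).
    """
    d = D.values
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")

    # BUILD: start with the 1-medoid minimiser, then greedily add the point
    # giving the largest decrease in total nearest-medoid distance.
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, d[:, c])

    medoids, objective = _swap_phase(d, np.array(medoids))
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            cand, cand_obj = _swap_phase(d, rng.choice(n, size=k, replace=False))
            if cand_obj < objective - 1e-12:
                medoids, objective = cand, cand_obj

    assign = _assign_to_medoids(d, medoids)
    assign[medoids] = np.arange(k)  # a medoid always anchors its own cluster
    labels = assign + 1
    part = Partition(labels=labels, k=k, method="pam")
    return PAMResult(partition=part, medoids=medoids, objective=float(objective))


def _objective(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def silhouette(D: DistanceMatrix, labels: np.ndarray) -> SilhouetteResult:
    """Per-sample silhouette widths s_i = (b_i - a_i)/max(a_i, b_i).

    a_i is the mean distance to the other members of the sample's own
    cluster, b_i the smallest mean distance to another cluster.  Singleton
    clusters get s_i = 0 by convention.
    """
    d = D.values
    labels = np.asarray(labels, dtype=int)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = d.shape[0]
    mean_to = np.empty((n, clusters.size))
    sizes = np.empty(clusters.size)
    for ci, c in enumerate(clusters):
        members = labels == c
        sizes[ci] = members.sum()
        mean_to[:, ci] = d[:, members].sum(axis=1)
    own = np.searchsorted(clusters, labels)
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        size_own = sizes[own[i]]
        other = np.delete(mean_to[i] / sizes, own[i])
        b[i] = other.min()
        if size_own > 1:
            a[i] = mean_to[i, own[i]] / (size_own - 1)
            s[i] = (b[i] - a[i]) / max(a[i], b[i])
        # singleton: a undefined, s stays 0
    return SilhouetteResult(a=a, b=b, widths=s, average=float(s.mean()))


def pamk_select(D: DistanceMatrix, k_range=range(2, 11),
                seed: int | None = None, n_restarts: int = 0) -> PAMResult:
    """Fit PAM for each k and keep the one maximising the average silhouette
    width (ties -> smallest k).  The full per-k trace is attached."""
    best: PAMResult | None = None
    trace: dict[int, float] = {}
    for k in k_range:
        res = pam(D, k, seed=seed, n_restarts=n_restarts)
        sil = silhouette(D, res.partition.labels)
        res.avg_silhouette = sil.average
        trace[k] = sil.average
        if best is None or sil.average > best.avg_silhouette + 1e-12:
            best = res
    if best is None:
        raise ValueError("empty k_range")
    best.silhouette_trace = trace
    return best


def ward_linkage(D: DistanceMatrix) -> Dendrogram:
    """Ward's minimum-variance agglomeration via the Lance–Williams update.

    Expects squared Euclidean input; merge height is the current
    between-cluster dissimilarity (so for two singletons the first merge
    height equals their squared distance).  Nearest-pair ties are broken by
    the lowest index pair.
    """
    if D.metric != "squared_euclidean":
        raise ValueError("ward_linkage requires a squared_euclidean DistanceMatrix")
    n = D.n
    d = D.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    ids = np.arange(n)

    child_a = np.empty(n - 1, dtype=int)
    child_b = np.empty(n - 1, dtype=int)
    heights = np.empty(n - 1)
    out_sizes = np.empty(n - 1, dtype=int)

    for t in range(n - 1):
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        flat = int(np.argmin(block))  # row-major -> lowest index pair on ties
        i, j = sub[flat // len(sub)], sub[flat % len(sub)]
        if i > j:
            i, j = j, i
        h = d[i, j]
        ni, nj = sizes[i], sizes[j]
        child_a[t], child_b[t] = ids[i], ids[j]
        heights[t] = h
        out_sizes[t] = int(ni + nj)

        # Lance–Williams Ward update into slot i
        nk = sizes[active]
        new = ((ni + nk) * d[i, active] + (nj + nk) * d[j, active] - nk * h) / (
            ni + nj + nk
        )
        d[i, active] = new
        d[active, i] = new
        d[i, i] = np.inf
        active[j] = False
        d[j, :] = np.inf
        d[:, j] = np.inf
        sizes[i] = ni + nj
        ids[i] = n + t
    return Dendrogram(n=n, child_a=child_a, child_b=child_b,
                      heights=heights, sizes=out_sizes)


def pct_change_heights(dend: Dendrogram, last_steps: int = 10) -> dict[int, float]:
    """Percent change in the agglomeration criterion going from N+1 to N clusters.

    pct(N) = 100 * (h(N) - h(N+1)) / h(N+1) where h(N) is the height of the
    merge that produces N clusters, reported for N = 1..last_steps.  A zero
    h(N+1) makes the percentage undefined (NaN, with a warning).
    """
    n = dend.n
    if last_steps > n - 2:
        raise ValueError(f"last_steps must be <= n-2 = {n - 2}")

    def h(N: int) -> float:
        # merge index (0-based) producing N clusters
        return float(dend.heights[n - N - 1])

    out: dict[int, float] = {}
    for N in range(1, last_steps + 1):
        denom = h(N + 1)
        if denom == 0:
            warnings.warn(f"pct change undefined at N={N}: h(N+1) = 0")
            out[N] = float("nan")
        else:
            out[N] = 100.0 * (h(N) - denom) / denom
    return out


def select_k_heights(dend: Dendrogram, last_steps: int = 10) -> int:
    """Stop the agglomeration before its most dissimilar join.

    The window's largest percent change at N clusters means the join from
    N+1 to N merged two well-separated clusters, so N+1 clusters are
    retained.  Ties go to the larger N+1.
    """
    pct = pct_change_heights(dend, last_steps)
    vals = {N: v for N, v in pct.items() if not np.isnan(v)}
    if not vals:
        raise ValueError("all percent changes undefined")
    best_v = max(vals.values())
    best_n = max(N for N, v in vals.items() if v >= best_v - 1e-12)
    return best_n + 1


def cut_tree(dend: Dendrogram, k: int) -> Partition:
    """Undo the last k-1 merges; labels are renumbered by first appearance."""
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    parent = np.arange(n + max(n - k, 0), dtype=int)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        new_id = n + t
        for child in (dend.child_a[t], dend.child_b[t]):
            parent[find(child)] = new_id
    roots = [find(i) for i in range(n)]
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return Partition(labels=labels, k=k, method="cut_tree")
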