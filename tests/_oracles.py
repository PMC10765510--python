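"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit loops, BFS, exhaustive
enumeration — and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import collections
from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# cluster-quality indices
# ---------------------------------------------------------------------------

def silhouette_brute(x: np.ndarray, labels: np.ndarray) -> float:
    n = len(x)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def calinski_harabasz_brute(x: np.ndarray, labels: np.ndarray) -> float:
    uniq = sorted(set(labels))
    k, n = len(uniq), len(x)
    z = x.mean(axis=0)
    between = within = 0.0
    for c in uniq:
        mem = x[np.asarray(labels) == c]
        zk = mem.mean(axis=0)
        between += len(mem) * np.sum((zk - z) ** 2)
        within += sum(np.sum((m - zk) ** 2) for m in mem)
    return (between / (k - 1)) / (within / (n - k))


def davies_bouldin_brute(x: np.ndarray, labels: np.ndarray) -> float:
    uniq = sorted(set(labels))
    k = len(uniq)
    cents = [x[np.asarray(labels) == c].mean(axis=0) for c in uniq]
    s = [np.mean([np.linalg.norm(m - cents[i]) for m in x[np.asarray(labels) == c]])
         for i, c in enumerate(uniq)]
    total = 0.0
    for i in range(k):
        total += max((s[i] + s[j]) / np.linalg.norm(cents[i] - cents[j])
                     for j in range(k) if j != i)
    return total / k


def inertia_brute(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in set(labels):
        mem = x[np.asarray(labels) == c]
        total += sum(np.sum((m - mem.mean(axis=0)) ** 2) for m in mem)
    return total


# ---------------------------------------------------------------------------
# graph indicators
# ---------------------------------------------------------------------------

def bfs_distances(a: np.ndarray) -> np.ndarray:
    n = len(a)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        queue = collections.deque([s])
        while queue:
            u = queue.popleft()
            for v in np.flatnonzero(a[u]):
                if not np.isfinite(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
    return dist


def global_efficiency_brute(a: np.ndarray) -> float:
    n = len(a)
    if n < 2:
        return 0.0
    dist = bfs_distances(a)
    acc = [1.0 / dist[i, j] if np.isfinite(dist[i, j]) else 0.0
           for i in range(n) for j in range(n) if i != j]
    return float(np.mean(acc))


def local_efficiency_brute(a: np.ndarray) -> float:
    n = len(a)
    vals = []
    for i in range(n):
        nb = np.flatnonzero(a[i])
        vals.append(global_efficiency_brute(a[np.ix_(nb, nb)]) if len(nb) >= 2 else 0.0)
    return float(np.mean(vals))


def clustering_brute(a: np.ndarray) -> float:
    vals = []
    for i in range(len(a)):
        nb = np.flatnonzero(a[i])
        d = len(nb)
        vals.append(0.0 if d < 2 else a[np.ix_(nb, nb)].sum() / (d * (d - 1)))
    return float(np.mean(vals))


def max_kcore_brute(a: np.ndarray) -> int:
    n = len(a)
    best = 0
    for k in range(0, n):
        al = a.copy()
        alive = np.ones(n, dtype=bool)
        while True:
            deg = al.sum(axis=1)
            drop = alive & (deg < k)
            if not drop.any():
                break
            alive[drop] = False
            al[drop, :] = 0
            al[:, drop] = 0
        if alive.any():
            best = k
        else:
            break
    return best


def assortativity_brute(a: np.ndarray) -> float:
    deg = a.sum(axis=1)
    xs, ys = [], []
    for i in range(len(a)):
        for j in range(len(a)):
            if a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs or np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def modularity_of_partition(a: np.ndarray, blocks: list[list[int]]) -> float:
    m = a.sum() / 2.0
    deg = a.sum(axis=1)
    q = 0.0
    for block in blocks:
        idx = np.asarray(block)
        lc = a[np.ix_(idx, idx)].sum() / 2.0
        dc = deg[idx].sum()
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def max_modularity_brute(a: np.ndarray) -> float:
    """Exhaustive search over all set partitions (feasible for n <= 7)."""

    def partitions(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    return max(modularity_of_partition(a, p) for p in partitions(list(range(len(a)))))


# ---------------------------------------------------------------------------
# Mann-Whitney by direct win counting
# ---------------------------------------------------------------------------

def mann_whitney_exact_brute(pre, post) -> float:
    """Two-sided exact p by enumerating group assignments and counting
    pairwise wins (+ half-ties) directly — no ranks involved."""

    def u_stat(g1, g2):
        return sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)

    pooled = list(pre) + list(post)
    n1 = len(pre)
    u_obs = u_stat(pre, post)
    crit = min(u_obs, n1 * len(post) - u_obs) + 1e-9
    hits = 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(g1, g2)
        if min(u, n1 * len(g2) - u) <= crit:
            hits += 1
    return hits / comb(len(pooled), n1)
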