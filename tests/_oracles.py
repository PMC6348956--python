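"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def taukr_statistic_loops(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rowwise Kendall Kr and tauKr by explicit double loops (NaN-aware)."""
    n = x.shape[0]
    kr = 0.0
    denom = 0.0
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        s = 0.0
        pairs = 0
        tx = ty = 0
        valid = [j for j in cols if not (math.isnan(x[i, j]) or math.isnan(y[i, j]))]
        for a_idx in range(len(valid)):
            for b_idx in range(a_idx + 1, len(valid)):
                j, k = valid[a_idx], valid[b_idx]
                sx = np.sign(x[i, j] - x[i, k])
                sy = np.sign(y[i, j] - y[i, k])
                s += sx * sy
                pairs += 1
                tx += sx == 0
                ty += sy == 0
        kr += s
        if pairs and pairs > tx and pairs > ty:
            denom += math.sqrt((pairs - tx) * (pairs - ty))
    if denom == 0:
        raise ZeroDivisionError("all rows tied")
    return kr, kr / denom


def betweenness_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Unnormalised geodesic betweenness by enumerating all shortest paths.

    Shortest-path lengths come from matrix powers of the adjacency matrix;
    paths are enumerated by depth-first search bounded at that length.
    """
    n = adj.shape[0]
    dist = shortest_path_lengths(adj)
    bet = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or dist[s, t] < 2:
                continue
            paths = _all_paths_of_length(adj, s, t, int(dist[s, t]))
            for path in paths:
                for v in path[1:-1]:
                    bet[v] += 1.0 / len(paths)
    return bet


def _all_paths_of_length(adj, s, t, length):
    paths = []

    def dfs(node, path):
        if len(path) - 1 == length:
            if node == t:
                paths.append(list(path))
            return
        for nxt in range(adj.shape[0]):
            if adj[node, nxt] and nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(s, [s])
    return paths


def shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted geodesic distances by Floyd-Warshall."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def reach_bruteforce(adj: np.ndarray) -> np.ndarray:
    d = shortest_path_lengths(adj)
    n = adj.shape[0]
    out = np.ones(n)
    for i in range(n):
        for j in range(n):
            if j != i and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out


def max_modularity_bruteforce(w: np.ndarray) -> float:
    """Maximum weighted Newman modularity over every partition (Bell-number search)."""
    n = w.shape[0]
    two_m = w.sum()
    k = w.sum(axis=1)

    def q_of(partition):
        q = 0.0
        for cluster in partition:
            idx = list(cluster)
            q += w[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
        return q

    best = -np.inf
    for partition in set_partitions(list(range(n))):
        best = max(best, q_of(partition))
    return best


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first, *subset]] + smaller[i + 1 :]
        yield [[first], *smaller]


def adi_loops(wins: np.ndarray) -> np.ndarray:
    """Average dominance index by per-opponent ratio loops."""
    n = wins.shape[0]
    out = np.zeros(n)
    for i in range(n):
        shares = []
        for j in range(n):
            if j == i:
                continue
            total = wins[i, j] + wins[j, i]
            if total > 0:
                shares.append(wins[i, j] / total)
        out[i] = float(np.mean(shares))
    return out


def kinship_coancestry(parents: dict[str, tuple[str | None, str | None]], order: list[str]):
    """Relatedness = 2 x coefficient of coancestry, by memoised recursion.

    ``order`` lists individuals oldest first; recursion always descends into
    the younger member of a pair.
    """
    pos = {ind: i for i, ind in enumerate(order)}
    memo: dict[tuple[str, str], float] = {}

    def f(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if pos[a] <= pos[b] else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            mo, fa = parents[a]
            val = 0.5 * (1.0 + f(mo, fa))
        else:
            young, old = (a, b) if pos[a] > pos[b] else (b, a)
            mo, fa = parents[young]
            val = 0.5 * (f(mo, old) + f(fa, old))
        memo[key] = val
        return val

    n = len(order)
    out = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            out[i, j] = 2.0 * f(a, b) if i != j else np.nan
    return out


def wls_normal_equations(x, y, w):
    """Closed-form weighted least squares with intercept: slope, intercept, s2, F."""
    xm = np.column_stack([np.ones_like(x), x])
    xtwx = xm.T @ np.diag(w) @ xm
    beta = np.linalg.solve(xtwx, xm.T @ (w * y))
    resid = y - xm @ beta
    dof = len(x) - 2
    s2 = float(np.sum(w * resid**2) / dof)
    se_slope = math.sqrt(s2 * np.linalg.inv(xtwx)[1, 1])
    f_stat = (beta[1] / se_slope) ** 2
    return float(beta[1]), float(beta[0]), s2, float(f_stat)


def wilcoxon_exact_p(diff: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    from scipy.stats import rankdata

    d = diff[diff != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean = ranks.sum() / 2.0
    count = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / total
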