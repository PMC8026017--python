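"""Independent brute-force oracles used to cross-check the main code.

These deliberately avoid networkx and the package's own algorithms:
reachability by boolean transitive closure, distances by Floyd-Warshall,
partial correlation by correlation-matrix inversion.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps


def _adjacency(tokens):
    nodes = sorted(set(tokens))
    index = {w: i for i, w in enumerate(nodes)}
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for u, v in zip(tokens, tokens[1:]):
        adj[index[u]][index[v]] = True
    return nodes, adj


def lsc_bruteforce(tokens) -> int:
    """Largest strongly connected component via transitive closure."""
    nodes, adj = _adjacency(tokens)
    n = len(nodes)
    reach = [[adj[i][j] for j in range(n)] for i in range(n)]
    for i in range(n):
        reach[i][i] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    best = 0
    for i in range(n):
        size = sum(1 for j in range(n) if reach[i][j] and reach[j][i])
        best = max(best, size)
    return best


def lcc_bruteforce(tokens) -> int:
    """Largest weak component via undirected transitive closure."""
    nodes, adj = _adjacency(tokens)
    n = len(nodes)
    reach = [[adj[i][j] or adj[j][i] or i == j for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    return max(sum(row) for row in reach)


def di_asp_bruteforce(tokens) -> tuple[float, float]:
    """Diameter and average shortest path by Floyd-Warshall.

    Undirected simple projection (self-loops dropped), restricted to the
    largest weak component, averaged over unordered node pairs.
    """
    nodes, adj = _adjacency(tokens)
    n = len(nodes)
    inf = math.inf
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and (adj[i][j] or adj[j][i]):
                dist[i][j] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    # largest weak component = largest set of mutually finite distances
    comps: list[list[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if dist[i][j] < inf]
        seen.update(comp)
        comps.append(comp)
    comp = max(comps, key=len)
    if len(comp) < 2:
        return 0.0, 0.0
    ds = [dist[i][j] for i, j in combinations(comp, 2)]
    return float(max(ds)), float(sum(ds) / len(ds))


def partial_spearman_inversion(x, y, z) -> tuple[float, float]:
    """Partial Spearman via inversion of the rank-correlation matrix."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z.reshape(-1, 1)
    n, k = z.shape[0], z.shape[1]
    ranks = np.column_stack(
        [sps.rankdata(x), sps.rankdata(y)]
        + [sps.rankdata(col) for col in z.T]
    )
    corr = np.corrcoef(ranks, rowvar=False)
    prec = np.linalg.inv(corr)
    r = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
    df = n - 2 - k
    t = r * math.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(r), p


def random_token_sequence(rng: np.random.Generator, max_len: int = 12):
    """Short random token list over a small alphabet (repeats likely)."""
    length = int(rng.integers(1, max_len + 1))
    alphabet = [chr(ord("a") + i) for i in range(int(rng.integers(1, 7)))]
    return [alphabet[int(rng.integers(len(alphabet)))] for _ in range(length)]
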