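"""Independent brute-force oracles used by the test suite.

These are deliberately written against the textbook recurrences (full 2-D
matrices, no rolling arrays, no traceback packing) so they share no code or
structure with the production kernels they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEG = -(10 ** 9)


def dp_align_score(q: str, s: str, sub: dict, gap_open: int, gap_extend: int,
                   local: bool) -> int:
    """Optimal affine-gap alignment score (gap of length L costs
    open + L*extend).  Full-matrix Gotoh, scores only."""
    n, m = len(q), len(s)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    if local:
        for i in range(n + 1):
            M[i][0] = 0
        for j in range(m + 1):
            M[0][j] = 0
    else:
        for i in range(1, n + 1):
            X[i][0] = -(gap_open + i * gap_extend)
        for j in range(1, m + 1):
            Y[0][j] = -(gap_open + j * gap_extend)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sc = sub[(q[i - 1], s[j - 1])]
            start = 0 if local else NEG
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1], start) + sc
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            if local:
                best = max(best, M[i][j])
    if local:
        return best
    return max(M[n][m], X[n][m], Y[n][m])


def blosum_dict(name: str = "BLOSUM62") -> dict:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return {(a, b): int(mat[a, b]) for a in aas for b in aas}


def hypergeom_tail_enumeration(c: int, N: int, a: int, b: int) -> float:
    """P[|A ∩ B| >= c] for uniformly random a- and b-subsets of [N],
    by enumerating all b-subsets against a fixed a-subset."""
    universe = list(range(N))
    A = set(universe[:a])
    total = 0
    hits = 0
    for B in itertools.combinations(universe, b):
        total += 1
        if len(A & set(B)) >= c:
            hits += 1
    return hits / total


def mannwhitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Returns (U of x, p).  Assumes no cross-group ties.  Two-sided p doubles
    the smaller tail (capped at 1), matching the classical convention.
    """
    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    pooled = sorted(list(x) + list(y))
    m = len(x)
    u_obs = u_stat(x, y)
    us = [u_stat(comb, [v for v in pooled if v not in set(comb)])
          for comb in itertools.combinations(pooled, m)]
    n_tot = len(us)
    lo = sum(1 for u in us if u <= u_obs) / n_tot
    hi = sum(1 for u in us if u >= u_obs) / n_tot
    return float(u_obs), min(1.0, 2.0 * min(lo, hi))


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random binary topology with positive branch lengths; returns
    (list of leaf names, {frozenset bipartitions}, distance matrix)."""
    names = [f"t{i}" for i in range(n_leaves)]
    # random sequential joining (yields a random unrooted binary tree)
    nodes = {i: ({names[i]}, {}) for i in range(n_leaves)}
    # adjacency with branch lengths
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        u = nxt
        nxt += 1
        adj[u] = []
        for child in (a, b):
            ln = 0.05 + float(rng.random())
            adj[u].append((child, ln))
            adj[child].append((u, ln))
        active = [k for k in active if k not in (a, b)] + [u]
    hub = nxt
    adj[hub] = []
    for child in active:
        ln = 0.05 + float(rng.random())
        adj[hub].append((child, ln))
        adj[child].append((hub, ln))

    # pairwise path distances
    import heapq

    def dists_from(src):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, v = heapq.heappop(heap)
            if d > dist.get(v, math.inf):
                continue
            for w, ln in adj[v]:
                nd = d + ln
                if nd < dist.get(w, math.inf):
                    dist[w] = nd
                    heapq.heappush(heap, (nd, w))
        return dist

    leaf_ids = list(range(n_leaves))
    D = np.zeros((n_leaves, n_leaves))
    for i in leaf_ids:
        d = dists_from(i)
        for j in leaf_ids:
            D[i, j] = d[j]

    # bipartitions: for each internal edge, the leaf set on one side
    universe = frozenset(names)
    bips = set()

    def leaves_below(v, parent):
        out = set()
        stack = [(v, parent)]
        while stack:
            node, par = stack.pop()
            if node < n_leaves:
                out.add(names[node])
            for w, _ln in adj[node]:
                if w != par:
                    stack.append((w, node))
        return out

    for v in adj:
        for w, _ln in adj[v]:
            if v < w:
                side = frozenset(leaves_below(w, v))
                if 1 < len(side) < n_leaves - 1:
                    other = universe - side
                    bips.add(side if len(side) < len(other)
                             else other if len(other) < len(side)
                             else min(side, other, key=lambda s: sorted(s)))
    import pandas as pd

    return names, bips, pd.DataFrame(D, index=names, columns=names)


def reference_mcl(edges, inflation=2.0, max_iter=200, tol=1e-8):
    """A small independent MCL (dense numpy, no pruning) for cross-checks."""
    nodes = sorted({n for u, v, _w in edges for n in (u, v)})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, w in edges:
        A[idx[u], idx[v]] = max(A[idx[u], idx[v]], w)
        A[idx[v], idx[u]] = max(A[idx[v], idx[u]], w)
    for i in range(n):
        A[i, i] = A[i].max() if A[i].max() > 0 else 1.0
    M = A / A.sum(0)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, 2) ** inflation
        new = new / new.sum(0)
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    support = (M > 1e-9) | (M.T > 1e-9)
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        stack = [i]
        comp = set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(j for j in range(n) if support[v, j])
        seen |= comp
        comps.append({nodes[j] for j in comp})
    return comps
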