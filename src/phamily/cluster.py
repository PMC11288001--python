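"""Completeness filtering, greedy dereplication, and Markov clustering.

These three operations are shared by the retrieval, orthology, and taxonomy
stages.  Completeness is a length proxy (fraction of the expected genome
length, capped at 1) rather than a trained estimator; dereplication follows
the CD-HIT convention (longest-first greedy assignment to the first centroid
clearing the identity and coverage-of-shorter gates); MCL is the standard
expansion/inflation iteration on a column-stochastic matrix with self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import GenomeRecord
from .align import nt_seed_extend


@dataclass
class DerepResult:
    centroids: list[str]
    member_of: dict[str, str]            # every input id -> centroid id
    stats: pd.DataFrame                  # member, centroid, identity, coverage

    def members(self, centroid: str) -> list[str]:
        return [m for m, c in self.member_of.items() if c == centroid]


@dataclass
class MclResult:
    clusters: list[set]
    inflation: float
    iterations: int

    def labels(self) -> dict:
        return {node: i for i, cl in enumerate(self.clusters) for node in cl}


def completeness_filter(genomes: list[GenomeRecord],
                        expected_len: int | str = "auto",
                        min_frac: float = 0.5,
                        trusted: list[GenomeRecord] | None = None,
                        ) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Drop genomes with length-proxy completeness below ``min_frac``.

    With ``expected_len="auto"`` the expectation is the median length of the
    supplied trusted complete genomes.  Completeness exactly at the threshold
    is retained (the drop condition is strictly below).
    """
    if expected_len == "auto":
        if not trusted:
            raise ValueError(
                "completeness_filter: expected_len='auto' needs >=1 trusted "
                "complete genome")
        expected = float(np.median([g.length_bp for g in trusted]))
    else:
        expected = float(expected_len)
        if expected <= 0:
            raise ValueError("expected_len must be positive")
    rows = []
    retained = []
    for g in genomes:
        comp = min(1.0, g.length_bp / expected)
        keep = comp >= min_frac
        rows.append({"genome": g.id, "length_bp": g.length_bp,
                     "completeness": round(comp, 4), "retained": keep})
    for g, row in zip(genomes, rows):
        if row["retained"]:
            retained.append(g)
    return retained, pd.DataFrame(rows)


def greedy_derep(seqs: list[GenomeRecord], id_min: float = 0.95,
                 short_cov_min: float = 0.80, k: int = 15,
                 ) -> DerepResult:
    """CD-HIT-style greedy nucleotide dereplication.

    Sequences are processed longest-first (ties broken by id); each joins the
    first existing centroid with alignment identity >= id_min and aligned
    coverage of the shorter sequence >= short_cov_min, else founds a new
    centroid.  Identity and coverage come from chained gapless segments of
    :func:`phamily.align.nt_seed_extend` (local identity, coverage of the
    shorter sequence).
    """
    order = sorted(seqs, key=lambda g: (-g.length_bp, g.id))
    centroids: list[GenomeRecord] = []
    member_of: dict[str, str] = {}
    rows = []
    for g in order:
        assigned = False
        for c in centroids:
            ident, cov = _pairwise_identity_cov(g, c, k=k)
            if ident >= id_min and cov >= short_cov_min:
                member_of[g.id] = c.id
                rows.append({"member": g.id, "centroid": c.id,
                             "identity": round(ident, 4),
                             "coverage": round(cov, 4)})
                assigned = True
                break
        if not assigned:
            centroids.append(g)
            member_of[g.id] = g.id
            rows.append({"member": g.id, "centroid": g.id,
                         "identity": 1.0, "coverage": 1.0})
    return DerepResult(
        centroids=[c.id for c in centroids], member_of=member_of,
        stats=pd.DataFrame(rows, columns=["member", "centroid", "identity",
                                          "coverage"]))


def _pairwise_identity_cov(a: GenomeRecord, b: GenomeRecord,
                           k: int = 15) -> tuple[float, float]:
    """Length-weighted identity and coverage-of-shorter from chained segments."""
    if min(a.length_bp, b.length_bp) < k:
        return 0.0, 0.0
    segs = nt_seed_extend(a.seq, b.seq, k=k,
                          query_id=a.id, subject_id=b.id)
    if not segs:
        return 0.0, 0.0
    total = sum(s.aligned_cols for s in segs)
    matches = sum(s.matches for s in segs)
    shorter = min(a.length_bp, b.length_bp)
    return matches / total, min(1.0, total / shorter)


def mcl(edges: list[tuple] | dict, inflation: float = 2.0,
        max_iter: int = 100, prune: float = 1e-5, tol: float = 1e-6,
        nodes: list | None = None) -> MclResult:
    """Markov clustering of a weighted undirected graph.

    ``edges``: (u, v, weight) triples (or {(u, v): weight}).  Self-loops with
    the node's maximum incident weight are added before column normalization;
    iteration alternates expansion (matrix square) and inflation (elementwise
    power + renormalization) until the matrix changes by less than ``tol``.
    Clusters are connected components of the limit matrix's support.
    Isolated explicit nodes become singleton clusters.
    """
    if isinstance(edges, dict):
        edges = [(u, v, w) for (u, v), w in edges.items()]
    node_set = set(nodes or [])
    for u, v, _w in edges:
        node_set.add(u)
        node_set.add(v)
    node_list = sorted(node_set)
    if not node_list:
        return MclResult(clusters=[], inflation=inflation, iterations=0)
    idx = {n: i for i, n in enumerate(node_list)}
    n = len(node_list)
    A = np.zeros((n, n))
    for u, v, w in edges:
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        i, j = idx[u], idx[v]
        A[i, j] = max(A[i, j], w)
        A[j, i] = max(A[j, i], w)
    # self-loops: each node's max incident weight (1 for isolated nodes)
    for i in range(n):
        mx = A[i].max()
        A[i, i] = mx if mx > 0 else 1.0
    M = A / A.sum(axis=0, keepdims=True)
    its = 0
    for its in range(1, max_iter + 1):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = inflated / colsum
        if np.max(np.abs(new - M)) < tol:
            M = new
            break
        M = new
    support = (M > 0) | (M.T > 0)
    import networkx as nx

    g = nx.from_numpy_array(support.astype(int))
    comps = [set(node_list[i] for i in comp)
             for comp in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), sorted(map(str, c))[0]))
    return MclResult(clusters=comps, inflation=inflation, iterations=its)
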