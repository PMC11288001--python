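"""Core-gene concatenation phylogenomics.

Per-gene multiple alignment is center-star (the sequence minimizing total
global-alignment distance to the others is the center; every other sequence
is merged against it under "once a gap, always a gap"), followed by
gap-column trimming, fixed-order concatenation, pairwise-deletion p-distance,
canonical neighbor joining (Saitou-Nei with the Studier-Keppler Q matrix),
and nonparametric column-bootstrap support.  This is a deliberately simple,
fully deterministic stand-in for an ML pipeline: its claim is clade recovery
on data of known structure, not likelihood-grade branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import global_protein
from .syndata import CORE_GENES


class PhyloError(ValueError):
    pass


@dataclass
class Msa:
    """A protein multiple alignment: gene name + {row id: aligned string}."""

    name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise PhyloError(f"MSA {self.name}: rows differ in length")

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class TreeNode:
    """Unrooted tree node; supports in [0, 100] on internal nodes."""

    name: str | None = None
    children: list = field(default_factory=list)
    length: float | None = None
    support: float | None = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set:
        return {l.name for l in self.leaves()}

    def bipartitions(self) -> set:
        """Non-trivial splits as frozensets of the smaller/canonical side."""
        all_leaves = frozenset(self.leaf_names())
        out = set()

        def walk(node):
            for c in node.children:
                below = frozenset(c.leaf_names())
                if 1 < len(below) < len(all_leaves) - 1:
                    out.add(_canon_split(below, all_leaves))
                walk(c)

        walk(self)
        return out

    def is_monophyletic(self, names: set) -> bool:
        names = frozenset(names)
        all_leaves = frozenset(self.leaf_names())
        if len(names) <= 1 or names == all_leaves:
            return True
        if len(names) == len(all_leaves) - 1:
            return True  # trivial split on an unrooted tree
        return _canon_split(names, all_leaves) in self.bipartitions()

    def clade_support(self, names: set) -> float | None:
        """Support of the internal node splitting ``names`` off, if present."""
        names = frozenset(names)
        all_leaves = frozenset(self.leaf_names())
        target = _canon_split(names, all_leaves)

        def walk(node):
            for c in node.children:
                below = frozenset(c.leaf_names())
                if _canon_split(below, all_leaves) == target \
                        and 1 < len(below) < len(all_leaves) - 1:
                    return c.support
                got = walk(c)
                if got is not None:
                    return got
            return None

        return walk(self)


def _canon_split(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: sorted(s))


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------

def center_star_msa(seqs: dict[str, str], name: str = "gene") -> Msa:
    """Center-star multiple alignment of >= 2 protein sequences.

    The center minimizes the sum of global-alignment distances
    (1 - identity) to all other sequences; other sequences are folded in
    pairwise under "once a gap, always a gap".
    """
    if len(seqs) < 2:
        raise PhyloError("center_star_msa needs >= 2 sequences")
    ids = sorted(seqs)
    n = len(ids)
    dist = np.zeros((n, n))
    aln_cache: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = global_protein(seqs[ids[i]], seqs[ids[j]])
            dist[i, j] = dist[j, i] = 1.0 - r.identity
            aln_cache[(i, j)] = _expand(seqs[ids[i]], seqs[ids[j]], r.cigar)
    center = int(np.argmin(dist.sum(axis=1)))
    master_center = seqs[ids[center]]
    rows: dict[str, str] = {ids[center]: master_center}
    for j in range(n):
        if j == center:
            continue
        if center < j:
            c_aln, s_aln = aln_cache[(center, j)]
        else:
            s_aln, c_aln = aln_cache[(j, center)]
        rows = _merge(rows, ids[center], c_aln, ids[j], s_aln)
    return Msa(name=name, rows={i: rows[i] for i in ids})


def _expand(q: str, s: str, cigar: str) -> tuple[str, str]:
    """Aligned strings from a global-alignment cigar."""
    qa, sa = [], []
    qi = si = 0
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
            continue
        run = int(num)
        num = ""
        if c == "M":
            qa.append(q[qi:qi + run])
            sa.append(s[si:si + run])
            qi += run
            si += run
        elif c == "I":
            qa.append(q[qi:qi + run])
            sa.append("-" * run)
            qi += run
        else:
            qa.append("-" * run)
            sa.append(s[si:si + run])
            si += run
    return "".join(qa), "".join(sa)


def _merge(rows: dict[str, str], center_id: str, c_aln: str,
           new_id: str, s_aln: str) -> dict[str, str]:
    """Merge a (center, new) pairwise alignment into the growing MSA."""
    master = rows[center_id]
    out = {rid: [] for rid in rows}
    new_row: list[str] = []
    mi = 0   # column in master
    pi = 0   # column in pairwise alignment
    ncol_m, ncol_p = len(master), len(c_aln)
    while mi < ncol_m or pi < ncol_p:
        m_char = master[mi] if mi < ncol_m else None
        p_char = c_aln[pi] if pi < ncol_p else None
        if m_char == "-" and (p_char != "-" or p_char is None):
            # master has an old gap column for the center; new row gets a gap
            for rid in rows:
                out[rid].append(rows[rid][mi])
            new_row.append("-")
            mi += 1
        elif p_char == "-" and (m_char != "-" or m_char is None):
            # new alignment inserts into the center; all old rows get a gap
            for rid in rows:
                out[rid].append("-")
            new_row.append(s_aln[pi])
            pi += 1
        else:
            # both emit the same center residue (or both gap columns)
            for rid in rows:
                out[rid].append(rows[rid][mi])
            new_row.append(s_aln[pi] if pi < ncol_p else "-")
            mi += 1
            pi += 1
    merged = {rid: "".join(chars) for rid, chars in out.items()}
    merged[new_id] = "".join(new_row)
    return merged


# ---------------------------------------------------------------------------
# trimming + concatenation
# ---------------------------------------------------------------------------

def trim_and_concat(msas: list[Msa], gap_frac_max: float = 0.5,
                    min_genes_shared: int = 4,
                    gene_order: tuple = CORE_GENES,
                    ) -> tuple[Msa, pd.DataFrame]:
    """Trim gappy columns per gene and concatenate in the declared order.

    A column is dropped when its gap fraction (over the rows that have the
    gene) exceeds ``gap_frac_max``.  Genomes present in fewer than
    ``min_genes_shared`` alignments are excluded with a warning; genomes
    missing one gene get an all-gap row for it.  Returns the concatenated
    MSA and a partition table (gene, start, end; 1-based inclusive).
    """
    by_name = {m.name: m for m in msas}
    ordered = [by_name[g] for g in gene_order if g in by_name]
    ordered += [m for m in msas if m.name not in gene_order]
    presence: dict[str, int] = {}
    for m in ordered:
        for rid in m.rows:
            presence[rid] = presence.get(rid, 0) + 1
    keep = sorted(r for r, c in presence.items() if c >= min_genes_shared)
    dropped = sorted(set(presence) - set(keep))
    if dropped:
        warnings.warn(
            f"excluded from concatenation (present in < {min_genes_shared} "
            f"gene alignments): {', '.join(dropped)}")
    if not keep:
        raise PhyloError("no genome passes min_genes_shared")
    parts = []
    concat = {rid: [] for rid in keep}
    pos = 0
    for m in ordered:
        arr = np.array([list(m.rows[r]) for r in m.rows])
        gap_frac = (arr == "-").mean(axis=0)
        cols = np.nonzero(gap_frac <= gap_frac_max)[0]
        trimmed = {rid: "".join(m.rows[rid][c] for c in cols)
                   for rid in m.rows}
        width = len(cols)
        for rid in keep:
            concat[rid].append(trimmed.get(rid, "-" * width))
        parts.append({"gene": m.name, "start": pos + 1, "end": pos + width})
        pos += width
    msa = Msa(name="concat", rows={r: "".join(v) for r, v in concat.items()})
    return msa, pd.DataFrame(parts, columns=["gene", "start", "end"])


# ---------------------------------------------------------------------------
# distances + neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(msa: Msa, min_cols: int = 10) -> pd.DataFrame:
    """Pairwise-deletion p-distance: 1 - identity over mutually non-gap cols."""
    ids = sorted(msa.rows)
    arrs = {r: np.frombuffer(msa.rows[r].encode(), dtype=np.uint8)
            for r in ids}
    gap = ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            both = (a != gap) & (b != gap)
            nc = int(both.sum())
            if nc < min_cols:
                raise PhyloError(
                    f"pair ({ids[i]}, {ids[j]}) shares only {nc} comparable "
                    f"columns (< {min_cols})")
            d[i, j] = d[j, i] = 1.0 - float((a[both] == b[both]).mean())
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_from_distance(dist: pd.DataFrame) -> TreeNode:
    """Canonical neighbor joining (Saitou-Nei, Studier-Keppler Q matrix).

    Returns an unrooted tree represented with a trifurcating root.  Negative
    branch lengths are clamped to 0.  Ties in Q are broken by (i, j) index
    order, so the topology is deterministic for a fixed row order.
    """
    ids = list(dist.index)
    if len(ids) < 3:
        raise PhyloError("nj needs >= 3 taxa")
    nodes = {i: TreeNode(name=ids[i]) for i in range(len(ids))}
    D = dist.to_numpy().astype(float).copy()
    active = list(range(len(ids)))
    nxt = len(ids)
    Dmap = {i: {j: D[i, j] for j in active if j != i} for i in active}
    while len(active) > 3:
        n = len(active)
        r = {i: sum(Dmap[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (n - 2) * Dmap[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _q, i, j = best
        dij = Dmap[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        u = nxt
        nxt += 1
        ni, nj_ = nodes.pop(i), nodes.pop(j)
        ni.length = max(0.0, li)
        nj_.length = max(0.0, lj)
        nodes[u] = TreeNode(children=[ni, nj_])
        Dmap[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (Dmap[i][k] + Dmap[j][k] - dij)
            Dmap[u][k] = duk
            Dmap[k][u] = duk
            del Dmap[k][i], Dmap[k][j]
        del Dmap[i], Dmap[j]
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    dij, dik, djk = Dmap[i][j], Dmap[i][k], Dmap[j][k]
    root = TreeNode()
    for node_id, ln in ((i, 0.5 * (dij + dik - djk)),
                        (j, 0.5 * (dij + djk - dik)),
                        (k, 0.5 * (dik + djk - dij))):
        nd = nodes.pop(node_id)
        nd.length = max(0.0, ln)
        root.children.append(nd)
    return root


def nj_tree(msa: Msa, bootstrap_n: int = 100, seed: int = 0) -> TreeNode:
    """NJ tree on pairwise-deletion p-distances with column bootstrap.

    Supports (bipartition frequency x 100) are attached to the internal
    nodes of the point-estimate tree; reproducible bit-for-bit for a fixed
    seed.
    """
    if len(msa.rows) < 4:
        raise PhyloError("a meaningful unrooted topology needs >= 4 rows")
    tree = nj_from_distance(p_distance_matrix(msa))
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        ids = sorted(msa.rows)
        ncol = msa.ncol
        mat = np.array([list(msa.rows[r]) for r in ids])
        for _b in range(bootstrap_n):
            cols = rng.integers(0, ncol, size=ncol)
            rep = Msa(name="bs", rows={
                ids[i]: "".join(mat[i, cols]) for i in range(len(ids))})
            try:
                rep_tree = nj_from_distance(p_distance_matrix(rep))
            except PhyloError:
                continue
            for bp in rep_tree.bipartitions():
                counts[bp] = counts.get(bp, 0) + 1
        universe = frozenset(msa.rows)

        def annotate(node):
            for c in node.children:
                below = frozenset(c.leaf_names())
                if 1 < len(below) < len(universe) - 1:
                    c.support = round(
                        100.0 * counts.get(_canon_split(below, universe), 0)
                        / bootstrap_n, 1)
                annotate(c)

        annotate(tree)
    return tree


def tree_path_length(tree: TreeNode, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""

    def find_path(node, target, path):
        if node.name == target and not node.children:
            return path
        for c in node.children:
            got = find_path(c, target, path + [c])
            if got is not None:
                return got
        return None

    pa = find_path(tree, a, [])
    pb = find_path(tree, b, [])
    if pa is None or pb is None:
        raise PhyloError(f"leaf not found: {a} or {b}")
    # drop the shared prefix of the two root-to-leaf paths
    k = 0
    while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
        k += 1
    return (sum(n.length or 0.0 for n in pa[k:])
            + sum(n.length or 0.0 for n in pb[k:]))
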