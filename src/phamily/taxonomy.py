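"""Classification engine: ortholog groups, core genes, AAI, shared-gene
fraction, gene-sharing network, proteomic distance, and subgroup delineation.

All operations consume one shared all-versus-all protein similarity table
(exact Smith-Waterman on every cross-genome protein pair), so the ortholog
graph, the AAI/shared-gene statistics, and the hypergeometric gene-sharing
network are guaranteed to agree on what a "hit" is.  Genus-level subgroups
are connected components of the genome graph gated at AAI > 60% and
shared-gene fraction > 0.5, labeled with roman numerals in decreasing size
order; size-1 components are reported as singletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .align import self_score, bit_score, evalue
from .cluster import mcl, MclResult

# gates, BLAST-convention (see align module for definitions)
ORTHO_GATES = dict(e_max=1e-3, id_min=0.25, cov_min=0.50)
NETWORK_GATES = dict(e_max=1e-5, bits_min=50.0)
AAI_GATES = dict(e_max=1e-3, id_min=0.25, cov_min=0.50)


@dataclass
class OrthoGroup:
    group_id: str
    members: list[tuple[str, str]]        # (genome_id, protein_id)
    label: str = ""

    @property
    def genomes(self) -> set:
        return {g for g, _p in self.members}

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PairwiseGenomeStats:
    genome_a: str
    genome_b: str
    aai: float | None            # percent; None when no RBH pair exists
    rbh_count: int
    shared_frac: float
    network_score: float = 0.0


@dataclass
class SubgroupAssignment:
    label_of: dict[str, str]
    aai_min: float
    shared_min: float
    method: str = "aai-components"

    def partition(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for g, lab in self.label_of.items():
            out.setdefault(lab, set()).add(g)
        return out


def all_vs_all(proteomes: dict[str, dict[str, str]],
               matrix: str = "BLOSUM62", bitscore_floor: float = 25.0,
               ) -> pd.DataFrame:
    """Exact local alignment of every cross-genome protein pair.

    Each unordered pair is scored once with a score-only Smith-Waterman
    pass; pairs reaching ``bitscore_floor`` bits get the full traceback and
    are reported in both orientations (coverages swapped).  The floor sits
    below the effective threshold of every downstream gate (the loosest,
    e-value 1e-3, needs ~30 bits even for the shortest proteins), so
    nothing the gates could keep is lost.  Columns: qid, sid, qgenome,
    sgenome, score, bitscore, identity, qcov, scov, evalue (search space
    |q|*|s|*n_proteins).
    """
    from . import _dp
    from .align import (alignment_stats, bit_score, encode_protein,
                        substitution_matrix)

    gids = sorted(proteomes)
    n_prot = sum(len(p) for p in proteomes.values())
    sub = substitution_matrix(matrix)
    codes = {pid: encode_protein(seq)
             for prots in proteomes.values() for pid, seq in prots.items()}
    lens = {pid: c.shape[0] for pid, c in codes.items()}
    import math

    from .align import KAPPA, LAMBDA

    raw_floor = (bitscore_floor * math.log(2.0) + math.log(KAPPA)) / LAMBDA
    rows = []
    for i, ga in enumerate(gids):
        for gb in gids[i + 1:]:
            for qid in proteomes[ga]:
                qc = codes[qid]
                for sid in proteomes[gb]:
                    sc = codes[sid]
                    if _dp.local_score_only(qc, sc, sub, 11, 1) < raw_floor:
                        continue
                    score, q0, s0, ops = _dp.align_seq(qc, sc, sub, 11, 1,
                                                       True)
                    bits = bit_score(score)
                    if bits < bitscore_floor:
                        continue
                    matches, qe, se = alignment_stats(qc, sc, q0, s0, ops)
                    cols = int(ops.size)
                    ev = evalue(score, lens[qid], lens[sid], n_prot)
                    ident = matches / cols if cols else 0.0
                    qcov = (qe - q0) / lens[qid]
                    scov = (se - s0) / lens[sid]
                    rows.append((qid, sid, ga, gb, float(score), bits,
                                 ident, qcov, scov, ev))
                    rows.append((sid, qid, gb, ga, float(score), bits,
                                 ident, scov, qcov, ev))
    return pd.DataFrame(
        rows, columns=["qid", "sid", "qgenome", "sgenome", "score",
                       "bitscore", "identity", "qcov", "scov", "evalue"])


def _gate(hits: pd.DataFrame, e_max=None, id_min=None, cov_min=None,
          bits_min=None) -> pd.DataFrame:
    m = pd.Series(True, index=hits.index)
    if e_max is not None:
        m &= hits.evalue <= e_max
    if id_min is not None:
        m &= hits.identity >= id_min
    if cov_min is not None:
        m &= hits.qcov >= cov_min
    if bits_min is not None:
        m &= hits.bitscore >= bits_min
    return hits[m]


def ortho_groups(proteomes: dict[str, dict[str, str]],
                 hits: pd.DataFrame | None = None,
                 inflation: float = 1.5, **gates) -> list[OrthoGroup]:
    """Ortholog clusters: gated similarity graph + Markov clustering.

    An edge joins two proteins when at least one orientation passes all the
    gates (e-value, identity, query coverage); edge weight is the bit score.
    Inflation defaults to 1.5 (the granularity orthology tools ship with:
    higher values shatter genus-level divergent orthologs into per-subgroup
    clusters).  Only clusters with >= 2 members are reported, ordered by
    size then id.
    """
    if len(proteomes) < 2:
        raise ValueError("ortho_groups needs >= 2 genomes")
    if hits is None:
        hits = all_vs_all(proteomes)
    use = {**ORTHO_GATES, **gates}
    gated = _gate(hits, **use)
    genome_of = {pid: g for g, prots in proteomes.items() for pid in prots}
    edges: dict[tuple[str, str], float] = {}
    for r in gated.itertuples():
        key = (r.qid, r.sid) if r.qid < r.sid else (r.sid, r.qid)
        edges[key] = max(edges.get(key, 0.0), r.bitscore)
    result = mcl([(u, v, w) for (u, v), w in edges.items()],
                 inflation=inflation)
    groups = []
    for cl in result.clusters:
        if len(cl) < 2:
            continue
        members = sorted((genome_of[p], p) for p in cl)
        groups.append(members)
    groups.sort(key=lambda m: (-len(m), m[0][1]))
    return [OrthoGroup(group_id=f"OG{i + 1:04d}", members=m)
            for i, m in enumerate(groups)]


def annotate_groups(groups: list[OrthoGroup], hallmark_hits) -> None:
    """Attach a hallmark profile label to groups containing a profile hit."""
    by_orf = {h.orf_id: h.profile for h in hallmark_hits}
    for g in groups:
        labels = sorted({by_orf[p] for _g, p in g.members if p in by_orf})
        g.label = ",".join(labels)


def core_genes(groups: list[OrthoGroup], genomes: list[str],
               core_frac: float = 1.0,
               hits: pd.DataFrame | None = None) -> list[OrthoGroup]:
    """Groups represented in >= core_frac of the genomes.

    When a genome contributes several members, one representative is kept:
    the protein with the highest mean identity to the rest of the group
    (ties broken by protein id), which requires the hit table.
    """
    need = core_frac * len(genomes)
    out = []
    for g in groups:
        if len(g.genomes) < need:
            continue
        members = g.members
        by_genome: dict[str, list[str]] = {}
        for gid, pid in members:
            by_genome.setdefault(gid, []).append(pid)
        reps = []
        group_pids = {p for _g, p in members}
        for gid in sorted(by_genome):
            pids = by_genome[gid]
            if len(pids) == 1 or hits is None:
                reps.append((gid, sorted(pids)[0]))
                continue
            sub = hits[(hits.qid.isin(pids)) & (hits.sid.isin(group_pids))]
            mean_id = sub.groupby("qid").identity.mean()
            best = sorted(pids, key=lambda p: (-mean_id.get(p, 0.0), p))[0]
            reps.append((gid, best))
        out.append(OrthoGroup(group_id=g.group_id, members=reps,
                              label=g.label))
    return out


def aai(genome_a: str, genome_b: str, proteomes: dict[str, dict[str, str]],
        hits: pd.DataFrame, **gates) -> PairwiseGenomeStats:
    """Average amino-acid identity as mean reciprocal-best-hit identity.

    Best hits are gated (e-value, identity, query coverage); AAI is the
    unweighted mean percent identity over RBH pairs (NA when none), and the
    shared-gene fraction is the RBH count over the smaller gene count.
    """
    pa, pb = proteomes[genome_a], proteomes[genome_b]
    if not pa or not pb:
        raise ValueError("aai: empty proteome")
    use = {**AAI_GATES, **gates}
    sub = hits[(hits.qgenome == genome_a) & (hits.sgenome == genome_b)]
    gated = _gate(sub, **use)
    best_ab = _best_by_query(gated)
    sub_r = hits[(hits.qgenome == genome_b) & (hits.sgenome == genome_a)]
    best_ba = _best_by_query(_gate(sub_r, **use))
    idents = []
    rbh = 0
    for q, (s, ident) in best_ab.items():
        back = best_ba.get(s)
        if back is not None and back[0] == q:
            rbh += 1
            idents.append(ident)
    return PairwiseGenomeStats(
        genome_a=genome_a, genome_b=genome_b,
        aai=100.0 * float(np.mean(idents)) if idents else None,
        rbh_count=rbh,
        shared_frac=rbh / min(len(pa), len(pb)))


def _best_by_query(gated: pd.DataFrame) -> dict[str, tuple[str, float]]:
    best: dict[str, tuple[float, str, float]] = {}
    for r in gated.itertuples():
        cur = best.get(r.qid)
        cand = (-r.bitscore, r.sid, r.identity)
        if cur is None or cand < cur:
            best[r.qid] = cand
    return {q: (sid, ident) for q, (_nb, sid, ident) in best.items()}


def pairwise_stats(proteomes: dict[str, dict[str, str]],
                   hits: pd.DataFrame) -> pd.DataFrame:
    """AAI / RBH / shared-gene fraction for every genome pair."""
    gids = sorted(proteomes)
    rows = []
    for i, ga in enumerate(gids):
        for gb in gids[i + 1:]:
            st = aai(ga, gb, proteomes, hits)
            rows.append({"genome_a": ga, "genome_b": gb,
                         "aai": st.aai, "rbh_count": st.rbh_count,
                         "shared_frac": st.shared_frac})
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "aai",
                                       "rbh_count", "shared_frac"])


# ---------------------------------------------------------------------------
# gene-sharing network
# ---------------------------------------------------------------------------

def protein_clusters(proteomes: dict[str, dict[str, str]],
                     hits: pd.DataFrame, inflation: float = 2.0) -> MclResult:
    """MCL protein clusters under the network gates (e<1e-5, bits>=50).

    Every protein is a node (singletons become their own cluster), matching
    the universe the hypergeometric test counts over.
    """
    gated = _gate(hits, **NETWORK_GATES)
    edges: dict[tuple[str, str], float] = {}
    for r in gated.itertuples():
        key = (r.qid, r.sid) if r.qid < r.sid else (r.sid, r.qid)
        edges[key] = max(edges.get(key, 0.0), r.bitscore)
    all_prots = [p for prots in proteomes.values() for p in prots]
    return mcl([(u, v, w) for (u, v), w in edges.items()], inflation=inflation,
               nodes=all_prots)


def hypergeom_sf(c: int, N: int, a: int, b: int) -> float:
    """P[X >= c] for X ~ Hypergeometric(N, a, b), exactly.

    Exact integer arithmetic for modest N; scipy's survival function (itself
    accurate to ~1e-14) for large universes.
    """
    if N < max(a, b):
        raise ValueError(f"inconsistent universe: N={N} < max(a={a}, b={b})")
    hi = min(a, b)
    if c <= 0:
        return 1.0
    if c > hi:
        return 0.0
    if N <= 1000:
        total = math.comb(N, b)
        acc = 0
        for i in range(c, hi + 1):
            acc += math.comb(a, i) * math.comb(N - a, b - i)
        return acc / total
    from scipy.stats import hypergeom

    return float(hypergeom.sf(c - 1, N, a, b))


def gene_sharing_network(proteomes: dict[str, dict[str, str]],
                         clusters: MclResult,
                         score_min: float = 1.0) -> pd.DataFrame:
    """Hypergeometric gene-sharing scores between genomes.

    For genomes with a and b protein clusters sharing c of an N-cluster
    universe, P is the hypergeometric tail P[X >= c] and the edge score is
    max(0, -log10 P - log10 T) with T the number of genome pairs; edges with
    score >= ``score_min`` are returned (source, target, shared, score).
    """
    label = clusters.labels()
    membership: dict[str, set[int]] = {}
    for gid, prots in proteomes.items():
        membership[gid] = {label[p] for p in prots if p in label}
    N = len(clusters.clusters)
    gids = sorted(proteomes)
    T = len(gids) * (len(gids) - 1) // 2
    rows = []
    for i, ga in enumerate(gids):
        for gb in gids[i + 1:]:
            a, b = len(membership[ga]), len(membership[gb])
            c = len(membership[ga] & membership[gb])
            p = hypergeom_sf(c, N, a, b)
            score = -math.log10(p) - math.log10(T) if p > 0 else math.inf
            score = max(0.0, score)
            if score >= score_min:
                rows.append({"source": ga, "target": gb, "shared": c,
                             "score": round(score, 4)})
    return pd.DataFrame(rows, columns=["source", "target", "shared", "score"])


# ---------------------------------------------------------------------------
# subgroup delineation
# ---------------------------------------------------------------------------

_ROMAN = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
          (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"),
          (4, "IV"), (1, "I")]


def _roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def delineate_subgroups(stats: pd.DataFrame, genomes: list[str],
                        aai_min: float = 60.0, shared_min: float = 0.5,
                        ) -> SubgroupAssignment:
    """Subgroups as connected components of the gated AAI graph.

    Edges require aai > aai_min (percent) AND shared_frac > shared_min.
    Components of size >= 2 get roman numerals in decreasing size order
    (ties: lexicographically smallest member id); singletons are labeled
    ``singleton-k`` in member-id order.  Output is independent of genome
    input order.
    """
    g = nx.Graph()
    g.add_nodes_from(genomes)
    for r in stats.itertuples():
        if r.aai is not None and not pd.isna(r.aai) \
                and r.aai > aai_min and r.shared_frac > shared_min:
            g.add_edge(r.genome_a, r.genome_b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    multi = sorted([c for c in comps if len(c) > 1],
                   key=lambda c: (-len(c), c[0]))
    single = sorted([c[0] for c in comps if len(c) == 1])
    label_of: dict[str, str] = {}
    for i, comp in enumerate(multi, start=1):
        for gid in comp:
            label_of[gid] = _roman(i)
    for k, gid in enumerate(single, start=1):
        label_of[gid] = f"singleton-{k}"
    return SubgroupAssignment(label_of=label_of, aai_min=aai_min,
                              shared_min=shared_min)


# ---------------------------------------------------------------------------
# proteomic distance
# ---------------------------------------------------------------------------

def proteomic_distance(genome_a: str, genome_b: str,
                       proteomes: dict[str, dict[str, str]],
                       hits: pd.DataFrame, **gates) -> float:
    """Normalized proteome similarity distance in [0, 1].

    S_AB sums each A protein's best gated hit bit score against B;
    distance = 1 - sym(S_AB, S_BA) / sqrt(S_AA * S_BB), 1 when no hits.
    """
    if genome_a == genome_b:
        return 0.0
    use = {**AAI_GATES, **gates}
    s_ab = _best_bits_sum(genome_a, genome_b, hits, use)
    s_ba = _best_bits_sum(genome_b, genome_a, hits, use)
    if s_ab == 0.0 and s_ba == 0.0:
        return 1.0
    s_aa = sum(bit_score(self_score(seq))
               for seq in proteomes[genome_a].values())
    s_bb = sum(bit_score(self_score(seq))
               for seq in proteomes[genome_b].values())
    d = 1.0 - 0.5 * (s_ab + s_ba) / math.sqrt(s_aa * s_bb)
    return float(min(1.0, max(0.0, d)))


def _best_bits_sum(ga: str, gb: str, hits: pd.DataFrame,
                   gates: dict) -> float:
    sub = _gate(hits[(hits.qgenome == ga) & (hits.sgenome == gb)], **gates)
    if sub.empty:
        return 0.0
    return float(sub.groupby("qid").bitscore.max().sum())


def distance_matrix(proteomes: dict[str, dict[str, str]],
                    hits: pd.DataFrame) -> pd.DataFrame:
    gids = sorted(proteomes)
    mat = pd.DataFrame(0.0, index=gids, columns=gids)
    for i, ga in enumerate(gids):
        for gb in gids[i + 1:]:
            d = proteomic_distance(ga, gb, proteomes, hits)
            mat.loc[ga, gb] = d
            mat.loc[gb, ga] = d
    return mat
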