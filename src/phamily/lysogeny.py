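"""Attachment-site detection, junction evidence from reads, and prophage calls.

Temperate phages integrate into their host by site-specific recombination
across a short identical core shared between the phage attP and the
bacterial attB (frequently inside a tRNA gene, which regenerates intact
after integration).  The finder enumerates all maximal exact matches between
a phage and a host genome, ranks tRNA-overlapping cores first, and predicts
the attL/attR junctions by Campbell arithmetic.  Junction detection looks
for reads that align partly to the phage and whose clipped tail aligns to
the host; prophage detection chains nucleotide segments of the phage query
inside bacterial contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import GenomeRecord, FeatureRecord, revcomp
from .align import nt_seed_extend, AlignmentResult


class LysogenyError(ValueError):
    pass


@dataclass
class AttSite:
    core: str
    phage_start: int                  # attP, 0-based half-open on the phage
    phage_end: int
    host_start: int                   # attB on the host
    host_end: int
    strand: str                       # '-' if the core matches reverse strand
    overlaps_host_trna: bool
    near_phage_trna: bool
    attL: tuple[int, int] | None = None   # predicted on the integrated map
    attR: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.phage_end - self.phage_start


@dataclass
class ProphageCall:
    contig_id: str
    phage_id: str
    start: int
    end: int
    mean_identity: float
    ref_coverage: float
    n_segments: int
    flank_start: int = 0          # host context window
    flank_end: int = 0


@dataclass
class JunctionCluster:
    breakpoint: int               # consensus position on the host/lysogen
    n_reads: int
    side: str                     # 'phage-left' or 'phage-right'


def find_att(phage: GenomeRecord, host: GenomeRecord,
             host_trnas: list[FeatureRecord] | None = None,
             phage_trnas: list[FeatureRecord] | None = None,
             min_len: int = 12, max_sites: int = 50) -> list[AttSite]:
    """All maximal exact matches >= min_len between phage and host genomes.

    Both strands are searched (k-mer anchor + bidirectional exact extension).
    Sites are ranked by (host-tRNA overlap desc, length desc, phage
    coordinate asc); attL/attR are predicted by Campbell integration
    arithmetic for the forward-strand geometry.
    """
    if min_len < 8:
        raise LysogenyError("min_len < 8 is below the noise floor")
    host_trnas = host_trnas or []
    phage_trnas = phage_trnas or []
    sites: list[AttSite] = []
    for strand in ("+", "-"):
        h_seq = host.seq if strand == "+" else revcomp(host.seq)
        for q0, s0, length in _maximal_exact_matches(phage.seq, h_seq,
                                                     min_len):
            if strand == "+":
                h0, h1 = s0, s0 + length
            else:
                h0, h1 = host.length_bp - (s0 + length), host.length_bp - s0
            core = phage.seq[q0:q0 + length]
            site = AttSite(
                core=core, phage_start=q0, phage_end=q0 + length,
                host_start=h0, host_end=h1, strand=strand,
                overlaps_host_trna=any(
                    f.kind == "tRNA" and h0 < f.end and f.start < h1
                    for f in host_trnas),
                near_phage_trna=any(
                    f.kind == "tRNA" and f.end <= q0 <= f.end + 500
                    for f in phage_trnas),
            )
            if strand == "+":
                # Campbell: lysogen = host[:attB) + core + phage arc + core
                # + host[attB+len:)
                site.attL = (h0, h1)
                site.attR = (h0 + phage.length_bp,
                             h0 + phage.length_bp + length)
            sites.append(site)
    sites.sort(key=lambda s: (not s.overlaps_host_trna, -s.length,
                              s.phage_start))
    return sites[:max_sites]


def _maximal_exact_matches(q: str, s: str, min_len: int
                           ) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= min_len as (qpos, spos, length) triples."""
    k = min_len
    index: dict[str, list[int]] = {}
    for j in range(len(s) - k + 1):
        index.setdefault(s[j:j + k], []).append(j)
    seen: set[tuple[int, int]] = set()   # (diagonal, start) of emitted MEMs
    out: list[tuple[int, int, int]] = []
    for i in range(len(q) - k + 1):
        for j in index.get(q[i:i + k], ()):
            # extend to a maximal match
            a, b = i, j
            while a > 0 and b > 0 and q[a - 1] == s[b - 1]:
                a -= 1
                b -= 1
            e1, e2 = i + k, j + k
            while e1 < len(q) and e2 < len(s) and q[e1] == s[e2]:
                e1 += 1
                e2 += 1
            key = (i - j, a)
            if key in seen:
                continue
            seen.add(key)
            out.append((a, b, e1 - a))
    return out


def verify_att(site: AttSite, phage: GenomeRecord, host: GenomeRecord) -> bool:
    """Re-verify a reported core by direct substring equality at both loci."""
    p = phage.seq[site.phage_start:site.phage_end]
    h = host.seq[site.host_start:site.host_end]
    if site.strand == "-":
        h = revcomp(h)
    return p == site.core and h == site.core


def att_report(sites: list[AttSite]) -> pd.DataFrame:
    from .seqio import to_one_based

    rows = []
    for s in sites:
        p1, p2 = to_one_based(s.phage_start, s.phage_end)
        h1, h2 = to_one_based(s.host_start, s.host_end)
        rows.append({
            "core": s.core, "length": s.length, "strand": s.strand,
            "phage_start": p1, "phage_end": p2,
            "host_start": h1, "host_end": h2,
            "overlaps_host_tRNA": s.overlaps_host_trna,
            "near_phage_tRNA": s.near_phage_trna,
        })
    return pd.DataFrame(rows, columns=[
        "core", "length", "strand", "phage_start", "phage_end", "host_start",
        "host_end", "overlaps_host_tRNA", "near_phage_tRNA"])


# ---------------------------------------------------------------------------
# junction detection from reads
# ---------------------------------------------------------------------------

def junction_detect(reads: list[tuple[str, str]], phage: GenomeRecord,
                    host: GenomeRecord, clip_min: int = 20,
                    id_min: float = 0.95, cluster_tol: int = 3,
                    min_reads: int = 2) -> list[JunctionCluster]:
    """Find attL/attR support: reads half in the phage, half in the host.

    A read whose best phage alignment leaves >= clip_min unaligned terminal
    bases, with the clipped part aligning to the host at >= id_min identity,
    contributes junction evidence at the host-side breakpoint (the host
    coordinate adjacent to the phage part in genome space); evidence within
    +-cluster_tol bp is clustered and clusters with >= min_reads reported.
    The two sides ('host-phage' and 'phage-host') bracket the att core on
    the host map.
    """
    from .align import NtIndex

    if reads and min(len(r[1]) for r in reads) < 2 * clip_min:
        raise LysogenyError("reads shorter than 2*clip_min")
    index = NtIndex([phage, host], k=15)
    evidence: list[tuple[int, str]] = []
    for _name, seq in reads:
        ev = _junction_evidence(seq, index, phage.id, host.id,
                                clip_min, id_min)
        if ev is not None:
            evidence.append(ev)
    evidence.sort()
    clusters: list[JunctionCluster] = []
    i = 0
    while i < len(evidence):
        j = i
        positions = [evidence[i][0]]
        sides = {evidence[i][1]: 1}
        while (j + 1 < len(evidence)
               and evidence[j + 1][0] - positions[-1] <= cluster_tol):
            j += 1
            positions.append(evidence[j][0])
            sides[evidence[j][1]] = sides.get(evidence[j][1], 0) + 1
        if len(positions) >= min_reads:
            side = max(sorted(sides), key=lambda s: sides[s])
            clusters.append(JunctionCluster(
                breakpoint=int(round(float(np.median(positions)))),
                n_reads=len(positions), side=side))
        i = j + 1
    return clusters


def _junction_evidence(seq: str, index, phage_id: str, host_id: str,
                       clip_min: int, id_min: float
                       ) -> tuple[int, str] | None:
    segs = index.map_segments(seq, probe_step=4)
    phits = [s for s in segs if s.subject_id == phage_id
             and s.identity >= id_min]
    if not phits:
        return None
    best = phits[0]
    n = len(seq)
    if best.q_start >= clip_min:
        clip_lo, clip_hi = 0, best.q_start
        host_left_of_phage_in_read = True
    elif n - best.q_end >= clip_min:
        clip_lo, clip_hi = best.q_end, n
        host_left_of_phage_in_read = False
    else:
        return None
    clip_len = clip_hi - clip_lo
    for h in segs:
        if (h.subject_id != host_id or h.identity < id_min
                or h.strand != best.strand):
            continue
        inter = min(h.q_end, clip_hi) - max(h.q_start, clip_lo)
        if inter < 0.9 * clip_len:
            continue
        # genome-space adjacency: on '+' segments read order == genome order
        host_left = (host_left_of_phage_in_read if h.strand == "+"
                     else not host_left_of_phage_in_read)
        if host_left:
            return h.s_end, "host-phage"
        return h.s_start, "phage-host"
    return None


# ---------------------------------------------------------------------------
# prophage detection
# ---------------------------------------------------------------------------

def find_prophage(phage_refs: list[GenomeRecord],
                  contigs: list[GenomeRecord], id_min: float = 0.95,
                  cov_min: float = 0.5, e_max: float = 1e-3,
                  max_segment_gap: int = 10_000, flank: int = 5_000,
                  ) -> list[ProphageCall]:
    """Phage-like islands in bacterial contigs by chained nucleotide segments.

    Segments of each phage query against each contig are chained when within
    ``max_segment_gap`` bp on the contig; a call requires chained coverage
    of the PHAGE reference >= cov_min and length-weighted identity >= id_min.
    Boundaries are the outermost chained segment ends; +-``flank`` bp of
    host context is annotated.
    """
    calls: list[ProphageCall] = []
    for contig in contigs:
        if contig.length_bp < 1_000:
            continue
        for ref in phage_refs:
            try:
                segs = nt_seed_extend(ref.seq, contig.seq, k=15,
                                      query_id=ref.id, subject_id=contig.id)
            except Exception:
                continue
            segs = [s for s in segs
                    if s.evalue is None or s.evalue <= e_max]
            if not segs:
                continue
            chain = _chain_segments(segs, max_segment_gap)
            total = sum(s.aligned_cols for s in chain)
            matches = sum(s.matches for s in chain)
            ref_cov = min(1.0, sum(s.q_aligned for s in chain)
                          / ref.length_bp)
            ident = matches / total if total else 0.0
            if ref_cov >= cov_min and ident >= id_min:
                start = min(s.s_start for s in chain)
                end = max(s.s_end for s in chain)
                calls.append(ProphageCall(
                    contig_id=contig.id, phage_id=ref.id,
                    start=start, end=end, mean_identity=ident,
                    ref_coverage=ref_cov, n_segments=len(chain),
                    flank_start=max(0, start - flank),
                    flank_end=min(contig.length_bp, end + flank)))
    calls.sort(key=lambda c: (c.contig_id, c.start, c.phage_id))
    return calls


def _chain_segments(segs: list[AlignmentResult], max_gap: int
                    ) -> list[AlignmentResult]:
    """Greedy chain: best-scoring segment plus compatible co-linear segments."""
    segs = sorted(segs, key=lambda s: (-s.score, s.s_start))
    chain = [segs[0]]
    for s in segs[1:]:
        if s.strand != chain[0].strand:
            continue
        lo = min(c.s_start for c in chain)
        hi = max(c.s_end for c in chain)
        if s.s_start >= hi - 50 and s.s_start - hi <= max_gap:
            chain.append(s)
        elif s.s_end <= lo + 50 and lo - s.s_end <= max_gap:
            chain.append(s)
    return chain


def prophage_gff(calls: list[ProphageCall], path) -> None:
    feats = [
        FeatureRecord(genome_id=c.contig_id, start=c.start, end=c.end,
                      strand="+", kind="other",
                      label=f"prophage:{c.phage_id} "
                            f"identity={c.mean_identity:.3f} "
                            f"coverage={c.ref_coverage:.3f}")
        for c in sorted(calls, key=lambda c: (c.contig_id, c.start))
    ]
    from .seqio import write_gff

    write_gff(feats, path)
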