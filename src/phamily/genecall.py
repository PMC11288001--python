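"""Minimal deterministic ORF caller (six-frame scan, translation table 11).

This is pipeline plumbing standing in for a trained gene finder: the synthetic
generator plants clean ORFs, and real-genome runs can import an external GFF
instead.  Starts are {ATG, GTG, TTG}; an ORF is the span from the leftmost
start to the stop codon of its stop-bounded frame segment, so nested starts
resolve deterministically to the longest ORF.  No partial calls at contig
edges.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GenomeRecord, FeatureRecord, revcomp, translate_cds

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GeneCall:
    """A called ORF in forward-strand 0-based half-open coordinates.

    ``end - start`` includes the stop codon; ``protein`` does not include a
    stop and starts with M regardless of the start codon (table 11).
    """

    genome_id: str
    start: int
    end: int
    strand: str
    protein: str
    gene_index: int = 0

    @property
    def id(self) -> str:
        return f"{self.genome_id}_ORF{self.gene_index}"

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


def call_orfs(genome: GenomeRecord, min_aa: int = 30,
              prune_nested: bool = False) -> list[GeneCall]:
    """Scan six frames for maximal ORFs with protein length >= min_aa.

    Within one stop-bounded segment of a frame only the longest ORF (leftmost
    start) is reported; overlapping calls on opposite strands are both kept.
    Output is sorted by (start, strand) and indexed 1-based in that order.

    ``prune_nested=True`` additionally resolves heavily overlapping calls —
    a deterministic stand-in for the coding-statistics models real gene
    finders apply to six-frame output, used by the pipeline so proteomes
    are not swamped by in-gene off-frame ORFs.  A call nested (>= 80% of
    its span) inside a call >= 1.25x longer is dropped outright; among
    near-equal overlapping calls (notably sense/antisense twins, which
    high-G+C coding regions produce routinely because reverse-strand stop
    codons are AT-rich) the call with the higher genome-trained
    codon-usage score wins.
    """
    if genome.length_bp < 3 * (min_aa + 1):
        raise ValueError(
            f"genome {genome.id} shorter than one minimal ORF "
            f"({3 * (min_aa + 1)} bp)"
        )
    calls: list[GeneCall] = []
    L = genome.length_bp
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        for frame in range(3):
            seg_start_codon: int | None = None  # first start codon seen
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    if seg_start_codon is not None:
                        orf_start = seg_start_codon
                        orf_end = pos + 3
                        n_codons = (orf_end - orf_start) // 3
                        if n_codons - 1 >= min_aa:
                            protein = "M" + translate_cds(
                                seq[orf_start + 3 : pos])
                            if strand == "+":
                                start, end = orf_start, orf_end
                            else:
                                start, end = L - orf_end, L - orf_start
                            calls.append(GeneCall(
                                genome_id=genome.id, start=start, end=end,
                                strand=strand, protein=protein))
                    seg_start_codon = None
                elif seg_start_codon is None and codon in START_CODONS:
                    seg_start_codon = pos
            # ORFs without an in-genome stop codon are not called
    if prune_nested:
        calls = _prune_overlaps(calls, genome)
    calls.sort(key=lambda c: (c.start, c.strand))
    for i, c in enumerate(calls, start=1):
        c.gene_index = i
    return calls


def _cds_nt(call: GeneCall, genome: GenomeRecord) -> str:
    nt = genome.seq[call.start:call.end]
    return nt if call.strand == "+" else revcomp(nt)


def _codon_usage(calls: list[GeneCall], genome: GenomeRecord,
                 min_aa: int = 100) -> dict[str, dict[str, int]]:
    """Per-amino-acid codon counts over all long calls (self-trained; true
    genes dominate the tally because every real gene contributes)."""
    counts: dict[str, dict[str, int]] = {}
    for c in calls:
        if len(c.protein) < min_aa:
            continue
        nt = _cds_nt(c, genome)
        for i in range(0, len(nt) - 3, 3):
            codon = nt[i:i + 3]
            aa = translate_cds(codon)
            counts.setdefault(aa, {})[codon] = \
                counts.get(aa, {}).get(codon, 0) + 1
    return counts


def _coding_score(call: GeneCall, genome: GenomeRecord,
                  usage: dict[str, dict[str, int]]) -> float:
    """Mean per-codon log2 likelihood ratio of the genome's synonymous
    codon usage against uniform synonymous choice."""
    import math

    nt = _cds_nt(call, genome)
    total = 0.0
    n = 0
    for i in range(0, len(nt) - 3, 3):
        codon = nt[i:i + 3]
        aa = translate_cds(codon)
        fam = usage.get(aa)
        if not fam:
            continue
        n_syn = len(fam)
        if n_syn < 2:
            continue
        tot = sum(fam.values())
        f = (fam.get(codon, 0) + 1) / (tot + n_syn)
        total += math.log2(f * n_syn)
        n += 1
    return total / n if n else 0.0


def _prune_overlaps(calls: list[GeneCall], genome: GenomeRecord,
                    frac: float = 0.8, margin: float = 1.25
                    ) -> list[GeneCall]:
    # stage 1: drop calls nested inside a much longer call
    by_len = sorted(calls,
                    key=lambda c: (-(c.end - c.start), c.start, c.strand))
    stage1: list[GeneCall] = []
    for c in by_len:
        span = c.end - c.start
        nested = False
        for k in stage1:
            if (k.end - k.start) < margin * span:
                continue
            inter = min(c.end, k.end) - max(c.start, k.start)
            if inter >= frac * span:
                nested = True
                break
        if not nested:
            stage1.append(c)
    # stage 2: among near-equal overlaps, the higher codon-usage score wins
    usage = _codon_usage(stage1, genome)
    scored = sorted(
        stage1,
        key=lambda c: (-round(_coding_score(c, genome, usage), 9),
                       c.start, c.strand))
    kept: list[GeneCall] = []
    for c in scored:
        span = c.end - c.start
        clash = False
        for k in kept:
            inter = min(c.end, k.end) - max(c.start, k.start)
            if inter >= frac * min(span, k.end - k.start):
                clash = True
                break
        if not clash:
            kept.append(c)
    return kept


def calls_to_features(calls: list[GeneCall]) -> list[FeatureRecord]:
    return [
        FeatureRecord(genome_id=c.genome_id, start=c.start, end=c.end,
                      strand=c.strand, kind="CDS", label=c.id)
        for c in calls
    ]


def proteome(calls: list[GeneCall]) -> dict[str, str]:
    """Proteins as an {orf_id: sequence} map in genome order."""
    return {c.id: c.protein for c in calls}
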