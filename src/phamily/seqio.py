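"""Sequence and feature I/O plus basic genome statistics.

This module owns the coordinate conventions for the whole package:

* internally every interval is **0-based half-open** ``[start, end)`` on the
  forward strand of its genome;
* every emitted text format (GFF3, BLAST-style tables, att reports) is
  **1-based inclusive**, converted through :func:`to_one_based` /
  :func:`from_one_based` and nowhere else.

Nucleotide sequences are upper-cased on input, ``U`` is mapped to ``T``, and
any character outside ``{A, C, G, T, N}`` is rejected: phage genome assemblies
with other ambiguity codes are not accepted rather than silently reinterpreted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_SOURCES = ("isolate", "uvig", "host", "synthetic")
_NT_OK = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqIOError(ValueError):
    """Raised for malformed sequence or feature input."""


@dataclass
class GenomeRecord:
    """A nucleotide sequence with provenance and derived statistics."""

    id: str
    seq: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"genome id must be a non-empty token, got {self.id!r}")
        if self.source not in VALID_SOURCES:
            raise SeqIOError(f"unknown source {self.source!r} for {self.id}")
        self.seq = normalize_nt(self.seq, context=self.id)
        if not self.seq:
            raise SeqIOError(f"genome {self.id} has an empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.seq)

    @property
    def length_kb(self) -> float:
        """Length in kb rounded to one decimal, the precision used in reports."""
        return round(self.length_bp / 1000.0, 1)

    def revcomp(self) -> "GenomeRecord":
        rec = GenomeRecord.__new__(GenomeRecord)
        rec.id = self.id
        rec.seq = revcomp(self.seq)
        rec.source = self.source
        return rec


@dataclass
class FeatureRecord:
    """A located feature (CDS, tRNA, ...) in internal 0-based half-open coords."""

    genome_id: str
    start: int
    end: int
    strand: str
    kind: str = "other"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"feature on {self.genome_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.kind not in ("CDS", "tRNA", "other"):
            raise SeqIOError(f"unknown feature kind {self.kind!r}")


def normalize_nt(seq: str, context: str = "sequence") -> str:
    """Upper-case, map U->T, reject anything outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    if not _NT_OK.match(s):
        pos = next(i for i, c in enumerate(s) if c not in "ACGTN")
        raise SeqIOError(
            f"{context}: invalid character {s[pos]!r} at position {pos + 1}"
        )
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(genome: GenomeRecord | str) -> float:
    """G+C fraction over called bases; N is excluded from both counts.

    Invariant under reverse complement.  Raises on an all-N sequence, where
    the statistic is undefined.
    """
    seq = genome.seq if isinstance(genome, GenomeRecord) else normalize_nt(genome)
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise SeqIOError("gc_content undefined: no called (non-N) bases")
    return gc / acgt


def format_percent(frac: float) -> str:
    """Fractions are reported as percent with two decimals (e.g. '52.85%')."""
    return f"{100.0 * frac:.2f}%"


# ---------------------------------------------------------------------------
# coordinate conversion (the only place it happens)
# ---------------------------------------------------------------------------

def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> emitted 1-based inclusive."""
    if not (0 <= start < end):
        raise SeqIOError(f"bad internal interval [{start}, {end})")
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """Emitted 1-based inclusive -> internal 0-based half-open."""
    if not (1 <= start1 <= end1):
        raise SeqIOError(f"bad 1-based interval [{start1}, {end1}]")
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, source: str = "synthetic") -> list[GenomeRecord]:
    """Read a (possibly gzipped) multi-FASTA of nucleotide sequences.

    Headers must be unique; the id is the first whitespace-delimited token.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    handle = _open_text(path)
    try:
        parsed = list(SeqIO.parse(handle, "fasta"))
    finally:
        handle.close()
    if not parsed:
        raise SeqIOError(f"{path}: no FASTA records found")
    for rec in parsed:
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, seq=str(rec.seq), source=source))
    return records


def write_fasta(records: Iterable[GenomeRecord] | dict[str, str],
                path: str | Path, width: int = 70) -> None:
    """Write records wrapped at ``width`` columns.

    Accepts either GenomeRecords or a plain ``{id: sequence}`` mapping (the
    latter is used for protein FASTA, which is not nucleotide-validated).
    """
    if isinstance(records, dict):
        items = records.items()
    else:
        items = ((r.id, r.seq) for r in records)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA as an ordered {id: sequence} map (gaps allowed)."""
    handle = _open_text(path)
    try:
        parsed = list(SeqIO.parse(handle, "fasta"))
    finally:
        handle.close()
    if not parsed:
        raise SeqIOError(f"{path}: no FASTA records found")
    out: dict[str, str] = {}
    for rec in parsed:
        if rec.id in out:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "?") -> None:
    """Write (name, sequence) reads at a constant Phred+33 quality (Q30='?')."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    handle = _open_text(path)
    try:
        return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fastq")]
    finally:
        handle.close()


def read_genbank(path: str | Path) -> tuple[GenomeRecord, list[FeatureRecord]]:
    """Read a GenBank flat file: the sequence plus CDS/tRNA features.

    Used for accession-based checks on deposited records; writing GenBank is
    out of scope.
    """
    handle = _open_text(path)
    try:
        rec = next(SeqIO.parse(handle, "genbank"))
    finally:
        handle.close()
    genome = GenomeRecord(id=rec.id, seq=str(rec.seq), source="isolate")
    feats: list[FeatureRecord] = []
    for f in rec.features:
        if f.type not in ("CDS", "tRNA"):
            continue
        label = ""
        for key in ("product", "gene", "locus_tag"):
            if key in f.qualifiers:
                label = f.qualifiers[key][0]
                break
        feats.append(FeatureRecord(
            genome_id=genome.id,
            start=int(f.location.start),
            end=int(f.location.end),
            strand="+" if f.location.strand != -1 else "-",
            kind=f.type,
            label=label,
        ))
    return genome, feats


def _open_text(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    if path.suffix == ".gz":
        import gzip

        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_KIND = {"CDS": "CDS", "tRNA": "tRNA", "other": "region"}
_GFF_KIND_REV = {v: k for k, v in _GFF_KIND.items()}


def write_gff(features: Sequence[FeatureRecord], path: str | Path,
              genome_lengths: dict[str, int] | None = None) -> None:
    """Write GFF3 (1-based inclusive) from internal 0-based features.

    Features must already be sorted by (genome_id, start).  If genome lengths
    are supplied, out-of-bounds features are rejected.
    """
    order = [(f.genome_id, f.start) for f in features]
    if order != sorted(order):
        raise SeqIOError("features must be sorted by (genome_id, start)")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if genome_lengths is not None:
                glen = genome_lengths.get(f.genome_id)
                if glen is not None and f.end > glen:
                    raise SeqIOError(
                        f"feature [{f.start},{f.end}) exceeds {f.genome_id} "
                        f"length {glen}"
                    )
            s1, e1 = to_one_based(f.start, f.end)
            attrs = f"label={_gff_escape(f.label)}" if f.label else "."
            fh.write(
                "\t".join([
                    f.genome_id, "phamily", _GFF_KIND[f.kind],
                    str(s1), str(e1), ".", f.strand, ".", attrs,
                ]) + "\n"
            )


def read_gff(path: str | Path) -> list[FeatureRecord]:
    feats: list[FeatureRecord] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SeqIOError(f"{path}: malformed GFF line: {line[:80]}")
            start, end = from_one_based(int(cols[3]), int(cols[4]))
            label = ""
            for item in cols[8].split(";"):
                if item.startswith("label="):
                    label = _gff_unescape(item[6:])
            feats.append(FeatureRecord(
                genome_id=cols[0], start=start, end=end, strand=cols[6],
                kind=_GFF_KIND_REV.get(cols[2], "other"), label=label,
            ))
    return feats


def _gff_escape(s: str) -> str:
    return s.replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace("\t", "%09")


def _gff_unescape(s: str) -> str:
    return s.replace("%09", "\t").replace("%3D", "=").replace("%3B", ";").replace("%25", "%")


# ---------------------------------------------------------------------------
# newick (used by the phylogeny module)
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialize a phylogeny.TreeNode to newick; returns the string."""
    text = _newick_str(tree) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def _newick_str(node) -> str:
    if not node.children:
        name = node.name or ""
        return f"{name}:{node.length:.6g}" if node.length is not None else name
    inner = ",".join(_newick_str(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:g}"
    out = f"({inner}){label}"
    if node.length is not None:
        out += f":{node.length:.6g}"
    return out


def parse_newick(text: str):
    """Parse newick into phylogeny.TreeNode (supports as internal labels)."""
    from .phylogeny import TreeNode

    text = text.strip()
    if not text.endswith(";"):
        raise SeqIOError("newick must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node():
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children:
                node.support = float(label)
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise SeqIOError(f"trailing newick text at position {pos}")
    return root


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate an in-frame CDS (without requiring a terminal stop)."""
    return str(Seq(nt).translate(table=table))
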