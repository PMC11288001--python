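"""Checks against the deposited reference records for the isolate and host.

These checks recompute, from locally supplied copies of the public records,
the descriptive statistics reported for the isolate phage CRP-810 and its
host FZCC0198: genome size (kb), G+C content, the amino-acid identity of its
terminase large subunit and tail fiber against pelagiphage homologs, and the
16S rRNA identity placing the host in the CHUG lineage.

The records themselves are not bundled; place them under ``data/accessions``
(any standard download of the accessions works):

    OR671924.gb              CRP-810 genome, GenBank flat file with CDS
    HTVC023P_TerL.faa        pelagiphage HTVC023P terminase large subunit
    HTVC025P_tail_fiber.faa  pelagiphage HTVC025P tail fiber protein
    PP816027.fasta           FZCC0198 16S rRNA gene
    HKCCA1288_16S.fasta      CHUG strain HKCCA1288 16S rRNA gene
"""

from __future__ import annotations

from pathlib import Path

from . import seqio
from .align import global_nt, local_protein
from .seqio import gc_content

REQUIRED_FILES = ("OR671924.gb", "HTVC023P_TerL.faa",
                  "HTVC025P_tail_fiber.faa", "PP816027.fasta",
                  "HKCCA1288_16S.fasta")


class MissingAccessionData(FileNotFoundError):
    pass


def _find_cds(features, *keywords):
    for f in features:
        label = f.label.lower()
        if all(k in label for k in keywords):
            return f
    return None


def run_accession_checks(data_dir: str | Path) -> dict:
    """Recompute the reference-record statistics from local files.

    Returns {genome_length_kb, gc_percent, terl_identity_pct,
    tail_fiber_identity_pct, ssu_identity_pct}.  Protein identities are
    local-alignment identities under the BLAST column convention; the 16S
    identity is the end-to-end nucleotide identity.
    """
    data_dir = Path(data_dir)
    missing = [f for f in REQUIRED_FILES if not (data_dir / f).exists()]
    if missing:
        raise MissingAccessionData(
            f"accession records not present under {data_dir}: "
            f"{', '.join(missing)} — download the public records and retry")
    genome, feats = seqio.read_genbank(data_dir / "OR671924.gb")
    out = {
        "genome_length_kb": genome.length_kb,
        "gc_percent": round(100.0 * gc_content(genome), 2),
    }
    terl_ref = next(iter(seqio.read_protein_fasta(
        data_dir / "HTVC023P_TerL.faa").values()))
    fiber_ref = next(iter(seqio.read_protein_fasta(
        data_dir / "HTVC025P_tail_fiber.faa").values()))
    terl = _find_cds(feats, "terminase", "large")
    fiber = _find_cds(feats, "tail", "fiber")
    for name, feat, ref in (("terl_identity_pct", terl, terl_ref),
                            ("tail_fiber_identity_pct", fiber, fiber_ref)):
        if feat is None:
            out[name] = None
            continue
        nt = genome.seq[feat.start:feat.end]
        if feat.strand == "-":
            nt = seqio.revcomp(nt)
        prot = seqio.translate_cds(nt[:-3] if nt[-3:] in
                                   ("TAA", "TAG", "TGA") else nt)
        out[name] = round(100.0 * local_protein(prot, ref).identity, 2)
    ssu_a = seqio.read_fasta(data_dir / "PP816027.fasta", source="host")[0]
    ssu_b = seqio.read_fasta(data_dir / "HKCCA1288_16S.fasta",
                             source="host")[0]
    out["ssu_identity_pct"] = round(
        100.0 * global_nt(ssu_a.seq, ssu_b.seq).identity, 2)
    return out
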