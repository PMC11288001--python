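"""Position-specific scoring models for hallmark genes, and family retrieval.

A profile is a log-odds PSSM built from a seed alignment (match columns =
columns with <= 50% gaps, +1 Laplace pseudocount against BLOSUM62 marginal
background frequencies).  Searching aligns each candidate protein to the
profile with affine gaps; a hit must clear ALL of: e-value, bit score, best-
seed identity, and profile coverage.  This is a deliberately small stand-in
for a Plan-7 profile HMM search with the same threshold semantics.

The retrieval cascade mirrors the field's standard mining recipe: three
hallmark profiles (terminase large subunit, major capsid protein,
primase-polymerase) are searched against every gene call of every candidate
contig, and a contig is retained if any profile yields a passing hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import (AA_INDEX, PROTEIN_ALPHABET, encode_protein, local_protein)
from . import _dp
from .genecall import GeneCall

HALLMARK_GENES = ("TerL", "capsid", "PrimPol")

# BLOSUM62 marginal amino-acid background frequencies (Henikoff counts).
_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


class ProfileError(ValueError):
    pass


@dataclass
class ProfileModel:
    """Log-odds PSSM over match columns of a seed alignment."""

    name: str
    columns: np.ndarray          # (length, 21) float64, bits; X column = 0
    seed_ids: list[str]
    seeds: dict[str, str]        # ungapped seed sequences
    background: np.ndarray       # (20,) frequencies

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])

    # per-column estimated residue frequencies (counts + pseudocount)
    frequencies: np.ndarray | None = None

    def consensus(self) -> str:
        """Most frequent residue per match column (by estimated frequency,
        not log-odds, so rare-residue pseudocounts cannot win a column)."""
        if self.frequencies is not None:
            idx = np.argmax(self.frequencies, axis=1)
        else:
            idx = np.argmax(self.columns[:, :20], axis=1)
        return "".join(PROTEIN_ALPHABET[i] for i in idx)


@dataclass
class HallmarkHit:
    contig_id: str
    orf_id: str
    profile: str
    bitscore: float
    seed_identity: float      # vs the closest seed, BLAST convention
    coverage: float           # aligned profile columns / profile length
    evalue: float


def background_frequencies() -> np.ndarray:
    bg = np.array([_BG[a] for a in PROTEIN_ALPHABET[:-1]])
    return bg / bg.sum()


def build_profile(seed_msa: dict[str, str], name: str) -> ProfileModel:
    """Build a PSSM from an aligned seed FASTA ({id: aligned sequence}).

    Match columns are those with at most 50% gap characters; per-column
    scores are log2((count + 1) / (n_obs + 20) / background).
    """
    if len(seed_msa) < 2:
        raise ProfileError("a profile needs at least 2 seed sequences")
    rows = list(seed_msa.values())
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ProfileError("seed alignment rows differ in length")
    bg = background_frequencies()
    nseq = len(rows)
    cols: list[np.ndarray] = []
    col_freqs: list[np.ndarray] = []
    for j in range(ncol):
        column = [r[j] for r in rows]
        gaps = sum(1 for c in column if c in "-.")
        if gaps * 2 > nseq:
            continue  # not a match column
        counts = np.zeros(20)
        for c in column:
            i = AA_INDEX.get(c.upper())
            if i is not None and i < 20:
                counts[i] += 1
        n_obs = counts.sum()
        freqs = (counts + 1.0) / (n_obs + 20.0)
        scores = np.zeros(21)
        scores[:20] = np.log2(freqs / bg)
        cols.append(scores)
        col_freqs.append(freqs)
    if not cols:
        raise ProfileError("no match columns (alignment is all gaps)")
    seeds = {sid: msa.replace("-", "").replace(".", "")
             for sid, msa in seed_msa.items()}
    return ProfileModel(name=name, columns=np.array(cols),
                        seed_ids=list(seed_msa), seeds=seeds,
                        background=bg, frequencies=np.array(col_freqs))


def search_profile(model: ProfileModel, proteins: list[GeneCall] | dict[str, str],
                   e_max: float = 1e-3, bits_min: float = 50.0,
                   id_min: float = 0.25, cov_min: float = 0.80,
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   ) -> list[HallmarkHit]:
    """Score every protein against the profile; return hits passing all gates.

    The PSSM raw score is already in bits (log2-odds), so it is used directly
    as the bit-like score; e-value = |protein| * profile_length * 2**(-bits).
    Seed identity is measured by local alignment against the best-scoring
    seed sequence.  Hits are sorted by bit score descending.
    """
    if isinstance(proteins, dict):
        items = [(pid, seq, pid.rsplit("_ORF", 1)[0])
                 for pid, seq in proteins.items()]
    else:
        items = [(c.id, c.protein, c.genome_id) for c in proteins]
    hits: list[HallmarkHit] = []
    for orf_id, seq, contig_id in items:
        if not seq:
            continue
        score, _q0, p0, ops = _dp.align_pssm(
            encode_protein(seq), model.columns, gap_open, gap_extend)
        if score <= 0:
            continue
        p_cols = int(np.sum(np.asarray(ops) != 1))  # ops consuming profile
        coverage = p_cols / model.length
        ev = len(seq) * model.length * math.pow(2.0, -score)
        if score < bits_min or ev > e_max or coverage < cov_min:
            continue
        seed_id = _best_seed_identity(seq, model)
        if seed_id < id_min:
            continue
        hits.append(HallmarkHit(
            contig_id=contig_id, orf_id=orf_id, profile=model.name,
            bitscore=float(score), seed_identity=seed_id,
            coverage=coverage, evalue=ev))
    hits.sort(key=lambda h: (-h.bitscore, h.orf_id))
    return hits


def _best_seed_identity(seq: str, model: ProfileModel) -> float:
    best_bits = -1.0
    best_ident = 0.0
    for sid in model.seed_ids:
        res = local_protein(seq, model.seeds[sid])
        if res.bitscore > best_bits:
            best_bits = res.bitscore
            best_ident = res.identity
    return best_ident


def retrieve_candidates(contig_calls: dict[str, list[GeneCall]],
                        models: list[ProfileModel],
                        **gates) -> tuple[list[str], pd.DataFrame]:
    """Retain contigs with >= 1 passing hallmark hit; emit the hit table."""
    all_hits: list[HallmarkHit] = []
    for calls in contig_calls.values():
        for model in models:
            all_hits.extend(search_profile(model, calls, **gates))
    retained = sorted({h.contig_id for h in all_hits})
    table = pd.DataFrame(
        [{"contig": h.contig_id, "orf": h.orf_id, "profile": h.profile,
          "bitscore": round(h.bitscore, 1),
          "seed_identity": round(h.seed_identity, 4),
          "coverage": round(h.coverage, 4), "evalue": h.evalue}
         for h in all_hits],
        columns=["contig", "orf", "profile", "bitscore", "seed_identity",
                 "coverage", "evalue"],
    )
    return retained, table


def hallmark_profiles_from_seeds(
        seed_msas: dict[str, dict[str, str]]) -> list[ProfileModel]:
    """Build the three hallmark profiles from {gene_name: seed MSA}."""
    return [build_profile(msa, name) for name, msa in seed_msas.items()]
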