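import pytest
from hypothesis import given, settings, strategies as st

from phamily import align
from phamily.align import (AlignError, global_protein, local_protein,
                           nt_seed_extend, self_score)

from _oracles import blosum_dict, dp_align_score

AA = "ACDEFGHIKLMNPQRSTVWY"
protein = st.text(alphabet=AA, min_size=1, max_size=50)


def test_self_alignment_identity_and_coverage():
    r = local_protein("MKVLA", "MKVLA")
    assert r.identity == 1.0 and r.q_cov == 1.0 and r.s_cov == 1.0
    assert r.score == self_score("MKVLA")


def test_textbook_local_blosum50_linear_gap():
    # classic worked example: HEAGAWGHEE vs PAWHEAE, BLOSUM50, linear -8
    r = local_protein("HEAGAWGHEE", "PAWHEAE", matrix="BLOSUM50",
                      gap_open=0, gap_extend=8)
    assert r.score == 28


def test_global_single_mismatch_column():
    r = global_protein("A", "G")
    assert r.aligned_cols == 1 and r.identity == 0.0 and r.matches == 0


def test_global_identical():
    r = global_protein("MKVLANDES", "MKVLANDES")
    assert r.identity == 1.0


def test_empty_sequence_rejected():
    with pytest.raises(AlignError):
        local_protein("", "MK")
    with pytest.raises(AlignError):
        global_protein("MK", "")


def test_reversed_scores_no_better_than_self(rng):
    s = "".join(rng.choice(list(AA), 50))
    assert local_protein(s[::-1], s).score <= self_score(s)


@pytest.mark.parametrize("local", [True, False], ids=["local", "global"])
def test_dp_matches_bruteforce_oracle_sample(local, rng):
    """Spot equivalence on 40 random pairs (the acceptance suite runs 200)."""
    sub = blosum_dict("BLOSUM62")
    for _ in range(40):
        q = "".join(rng.choice(list(AA), rng.integers(1, 61)))
        s = "".join(rng.choice(list(AA), rng.integers(1, 61)))
        expect = dp_align_score(q, s, sub, 11, 1, local)
        got = (local_protein if local else global_protein)(q, s).score
        assert got == expect, (q, s)


@settings(derandomize=True, max_examples=40)
@given(protein, protein)
def test_score_symmetry_and_integer_matches(q, s):
    a = local_protein(q, s)
    b = local_protein(s, q)
    assert a.score == b.score
    # identity * aligned_cols is the (integer) match count
    assert a.matches == round(a.identity * a.aligned_cols)
    assert 0.0 <= a.identity <= 1.0


def test_cigar_consistent_with_score():
    r = global_protein("MKVLAW", "MKVAW")
    consumed_q = sum(n for n, op in align._cigar_runs(r.cigar) if op in "MI")
    consumed_s = sum(n for n, op in align._cigar_runs(r.cigar) if op in "MD")
    assert consumed_q == 6 and consumed_s == 5


# ---------------------------------------------------------------------------
# nucleotide seed-and-extend
# ---------------------------------------------------------------------------

def test_nt_embedded_subject_found(rng):
    s = "".join(rng.choice(list("ACGT"), 300))
    q = ("".join(rng.choice(list("ACGT"), 100)) + s
         + "".join(rng.choice(list("ACGT"), 100)))
    hits = nt_seed_extend(q, s)
    assert hits and hits[0].identity == 1.0 and hits[0].s_cov == 1.0


def test_nt_five_percent_substitutions(rng):
    s = "".join(rng.choice(list("ACGT"), 1000))
    q = list(s)
    for i in rng.choice(1000, 50, replace=False):
        q[i] = str(rng.choice([c for c in "ACGT" if c != q[i]]))
    hits = nt_seed_extend("".join(q), s)
    assert 0.93 <= hits[0].identity <= 0.97


def test_nt_no_shared_kmers():
    assert nt_seed_extend("A" * 100, "C" * 100) == []


def test_nt_reverse_strand(rng):
    from phamily.seqio import revcomp

    s = "".join(rng.choice(list("ACGT"), 200))
    hits = nt_seed_extend(revcomp(s), s)
    assert hits[0].strand == "-" and hits[0].identity == 1.0


def test_nt_k_validation():
    with pytest.raises(AlignError):
        nt_seed_extend("ACGTACGT", "ACGTACGT", k=20)


def test_blast6_table_columns(rng):
    s = "".join(rng.choice(list("ACGT"), 120))
    hits = nt_seed_extend(s, s, query_id="q", subject_id="s")
    df = align.blast6_table(hits)
    assert list(df.columns) == align.BLAST6_COLUMNS
    assert df.iloc[0].pident == 100.0 and df.iloc[0].qstart == 1


def test_nt_index_matches_seed_extend(rng):
    from phamily.align import NtIndex
    from phamily.seqio import GenomeRecord

    ref = GenomeRecord("r1", "".join(rng.choice(list("ACGT"), 2000)))
    read = ref.seq[700:850]
    segs = NtIndex([ref]).map_segments(read)
    assert segs[0].subject_id == "r1"
    assert segs[0].s_start == 700 and segs[0].identity == 1.0
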