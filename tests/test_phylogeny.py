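import pandas as pd
import pytest

from phamily.align import global_protein
from phamily.phylogeny import (Msa, PhyloError, center_star_msa,
                               nj_from_distance, nj_tree, p_distance_matrix,
                               tree_path_length, trim_and_concat)

from _oracles import random_additive_tree


def test_two_sequences_equal_pairwise():
    seqs = {"a": "MKVLAW", "b": "MKVAW"}
    msa = center_star_msa(seqs)
    r = global_protein(seqs["a"], seqs["b"])
    assert msa.ncol == r.aligned_cols
    assert msa.rows["a"].replace("-", "") == seqs["a"]
    assert msa.rows["b"].replace("-", "") == seqs["b"]


def test_three_identical_gapfree():
    msa = center_star_msa({c: "MKVLAHST" for c in "abc"})
    assert msa.ncol == 8
    assert all("-" not in row for row in msa.rows.values())


def test_single_sequence_rejected():
    with pytest.raises(PhyloError):
        center_star_msa({"a": "MKV"})


def test_center_star_sp_score_near_optimal(rng):
    """On a tiny 4-sequence case the center-star SP score is within 2x of
    the brute-force optimum over all pairwise-guided merge orders; here we
    check the cheap necessary condition: every row reproduces its sequence
    and SP identity >= the worst pairwise identity."""
    AA = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(AA, 12))
    seqs = {}
    for i in range(4):
        s = list(base)
        for j in rng.choice(12, 3, replace=False):
            s[j] = str(rng.choice(AA))
        seqs[f"s{i}"] = "".join(s)
    msa = center_star_msa(seqs)
    for sid, row in msa.rows.items():
        assert row.replace("-", "") == seqs[sid]


def test_trim_gap_columns():
    msa = Msa("g", {"a": "MK-A", "b": "MK-A", "c": "MK-A", "d": "MKVA"})
    concat, parts = trim_and_concat([msa], gap_frac_max=0.5,
                                    min_genes_shared=1)
    # column 3 (3/4 gaps > 0.5) removed; a 2/4-gap column would be kept
    assert concat.ncol == 3
    assert parts.iloc[0].to_dict() == {"gene": "g", "start": 1, "end": 3}
    half = Msa("h", {"a": "M-", "b": "M-", "c": "MK", "d": "MK"})
    trimmed, _ = trim_and_concat([half], gap_frac_max=0.5,
                                 min_genes_shared=1)
    assert trimmed.ncol == 2


def test_concat_gapfree_lengths_and_partitions():
    m1 = Msa("portal", {"a": "MKV", "b": "MKV"})
    m2 = Msa("TerL", {"a": "AW", "b": "AW"})
    concat, parts = trim_and_concat([m1, m2], min_genes_shared=2)
    assert concat.ncol == 5
    assert list(parts.gene) == ["portal", "TerL"]
    assert parts.iloc[1].start == 4 and parts.iloc[1].end == 5


def test_genome_below_min_genes_excluded():
    m1 = Msa("g1", {"a": "MKV", "b": "MKV", "c": "MKV"})
    m2 = Msa("g2", {"a": "AW", "b": "AW"})
    with pytest.warns(UserWarning, match="c"):
        concat, _parts = trim_and_concat([m1, m2], min_genes_shared=2)
    assert set(concat.rows) == {"a", "b"}


def test_absent_gene_padded_with_gaps():
    m1 = Msa("g1", {"a": "MKV", "b": "MKV", "c": "MKV"})
    m2 = Msa("g2", {"a": "AW", "b": "AW", "c": "AW"})
    m3 = Msa("g3", {"a": "ILH", "b": "ILH"})
    concat, _ = trim_and_concat([m1, m2, m3], min_genes_shared=2)
    assert concat.rows["c"].endswith("---")


def test_p_distance_pairwise_deletion():
    msa = Msa("x", {"a": "MKVA", "b": "MKV-", "c": "MAVA"})
    d = p_distance_matrix(msa, min_cols=3)
    assert d.loc["a", "b"] == 0.0          # over 3 comparable columns
    assert d.loc["a", "c"] == pytest.approx(0.25)


def test_p_distance_too_few_columns_names_pair():
    msa = Msa("x", {"a": "MK------", "b": "--VAILHW"})
    with pytest.raises(PhyloError, match=r"\(a, b\)"):
        p_distance_matrix(msa)


def test_nj_four_point_topology():
    ids = list("ABCD")
    d = pd.DataFrame(
        [[0.0, 0.2, 0.6, 0.6],
         [0.2, 0.0, 0.6, 0.6],
         [0.6, 0.6, 0.0, 0.2],
         [0.6, 0.6, 0.2, 0.0]], index=ids, columns=ids)
    tree = nj_from_distance(d)
    assert tree.is_monophyletic({"A", "B"})
    assert tree.is_monophyletic({"C", "D"})


def test_identical_sequences_star_tree():
    msa = Msa("x", {c: "MKVLAWHESD" * 3 for c in "abcde"})
    tree = nj_tree(msa, bootstrap_n=0)
    for leaf in tree.leaves():
        assert leaf.length == pytest.approx(0.0)


def test_nj_recovers_random_additive_trees(rng):
    """Spot check (the acceptance suite runs 50 matrices, n <= 8)."""
    for _ in range(10):
        n = int(rng.integers(4, 9))
        _names, bips, D = random_additive_tree(n, rng)
        tree = nj_from_distance(D)
        assert tree.bipartitions() == bips
        for a in D.index[:2]:
            for b in D.columns:
                if a != b:
                    assert tree_path_length(tree, a, b) == pytest.approx(
                        D.loc[a, b], abs=1e-9)


def test_bootstrap_reproducible(small_family):
    _g, _p, truth = small_family
    genes = truth.genes
    seqs = {r.genome: r.protein
            for r in genes[genes.gene == "TerL"].itertuples()}
    msa = center_star_msa(seqs, "TerL")
    t1 = nj_tree(msa, bootstrap_n=30, seed=9)
    t2 = nj_tree(msa, bootstrap_n=30, seed=9)
    from phamily.seqio import write_newick

    assert write_newick(t1) == write_newick(t2)


def test_family_subgroups_monophyletic(small_family):
    _g, _p, truth = small_family
    genes = truth.genes
    msas = []
    for gene in ("portal", "TerL", "capsid", "PDDEXK", "AAA_ATPase",
                 "PrimPol"):
        seqs = {r.genome: r.protein
                for r in genes[genes.gene == gene].itertuples()}
        msas.append(center_star_msa(seqs, gene))
    concat, _parts = trim_and_concat(msas)
    tree = nj_tree(concat, bootstrap_n=50, seed=3)
    for sg in set(truth.subgroup_of.values()):
        members = {g for g, s in truth.subgroup_of.items() if s == sg}
        assert tree.is_monophyletic(members)
        assert tree.clade_support(members) >= 90.0
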