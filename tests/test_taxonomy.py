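import math

import pandas as pd
import pytest
from scipy import stats as sps

from phamily import taxonomy
from phamily.taxonomy import (aai, all_vs_all, core_genes,
                              delineate_subgroups, gene_sharing_network,
                              hypergeom_sf, ortho_groups, pairwise_stats,
                              protein_clusters, proteomic_distance)

from _oracles import hypergeom_tail_enumeration


@pytest.fixture(scope="module")
def identical_pair(rng):
    AA = list("ACDEFGHIKLMNPQRSTVWY")
    prots = {f"gA_ORF{i + 1}": "".join(rng.choice(AA, 120)) for i in range(5)}
    pb = {pid.replace("gA", "gB"): s for pid, s in prots.items()}
    return {"gA": prots, "gB": pb}


@pytest.fixture(scope="module")
def random_pair(rng):
    AA = list("ACDEFGHIKLMNPQRSTVWY")
    return {
        "gA": {f"gA_ORF{i + 1}": "".join(rng.choice(AA, 120))
               for i in range(5)},
        "gB": {f"gB_ORF{i + 1}": "".join(rng.choice(AA, 120))
               for i in range(5)},
    }


def test_identical_proteomes_n_groups_aai_100(identical_pair):
    hits = all_vs_all(identical_pair)
    groups = ortho_groups(identical_pair, hits=hits)
    assert len(groups) == 5 and all(g.size == 2 for g in groups)
    st = aai("gA", "gB", identical_pair, hits)
    assert st.aai == pytest.approx(100.0)
    assert st.shared_frac == 1.0


def test_unrelated_proteomes_no_groups_aai_na(random_pair):
    hits = all_vs_all(random_pair)
    assert ortho_groups(random_pair, hits=hits) == []
    st = aai("gA", "gB", random_pair, hits)
    assert st.rbh_count == 0 and st.aai is None


def test_empty_proteome_rejected(identical_pair):
    hits = all_vs_all(identical_pair)
    broken = {"gA": identical_pair["gA"], "gB": {}}
    with pytest.raises(ValueError):
        aai("gA", "gB", broken, hits)


def test_family_core_groups_match_truth(small_family, small_hits):
    _g, proteomes, truth = small_family
    groups = ortho_groups(proteomes, hits=small_hits)
    gids = sorted(proteomes)
    core = core_genes(groups, gids, 1.0, hits=small_hits)
    # each core group is exactly one planted core gene across all genomes
    core_sets = [{p for _g, p in g.members} for g in core]
    for gene in ("portal", "TerL", "capsid", "PDDEXK", "AAA_ATPase",
                 "PrimPol"):
        planted = {f"{g}|{gene}" for g in gids}
        assert planted in core_sets
    assert len(core) == 6


def test_core_frac_zero_returns_all(small_family, small_hits):
    _g, proteomes, _t = small_family
    groups = ortho_groups(proteomes, hits=small_hits)
    assert len(core_genes(groups, sorted(proteomes), 0.0)) == len(groups)


def test_group_missing_one_genome_excluded(small_family, small_hits):
    _g, proteomes, _t = small_family
    groups = ortho_groups(proteomes, hits=small_hits)
    partial = [g for g in groups if len(g.genomes) == len(proteomes) - 1]
    if partial:
        core = core_genes(groups, sorted(proteomes), 1.0)
        assert all(g.group_id != partial[0].group_id for g in core)


def test_aai_matches_planted_identity(small_family, small_hits):
    _g, proteomes, truth = small_family
    stats = pairwise_stats(proteomes, small_hits)
    merged = stats.merge(truth.pair_identity, on=["genome_a", "genome_b"])
    assert ((merged.aai - 100 * merged.identity).abs() <= 3.0).all()


def test_aai_symmetric(small_family, small_hits):
    _g, proteomes, _t = small_family
    a, b = sorted(proteomes)[:2]
    ab = aai(a, b, proteomes, small_hits)
    ba = aai(b, a, proteomes, small_hits)
    assert ab.aai == pytest.approx(ba.aai)
    assert ab.rbh_count == ba.rbh_count


# ---------------------------------------------------------------------------
# hypergeometric network score
# ---------------------------------------------------------------------------

def test_hypergeom_exact_combinatorial_example():
    # all clusters shared: a=b=c=5, N=10 -> P = 1/C(10,5) = 1/252
    p = hypergeom_sf(5, 10, 5, 5)
    assert p == pytest.approx(1.0 / 252.0)
    assert -math.log10(p) == pytest.approx(math.log10(252.0))


def test_hypergeom_matches_enumeration_small():
    for N, a, b, c in [(6, 3, 3, 2), (8, 4, 5, 3), (10, 5, 5, 5),
                       (12, 6, 4, 2), (7, 2, 5, 1)]:
        assert hypergeom_sf(c, N, a, b) == pytest.approx(
            hypergeom_tail_enumeration(c, N, a, b))


def test_hypergeom_matches_scipy_large():
    assert hypergeom_sf(40, 1500, 60, 70) == pytest.approx(
        float(sps.hypergeom.sf(39, 1500, 60, 70)), rel=1e-9)


def test_hypergeom_inconsistent_universe():
    with pytest.raises(ValueError):
        hypergeom_sf(1, 5, 6, 3)


def test_network_within_above_between(small_family, small_hits):
    _g, proteomes, truth = small_family
    clusters = protein_clusters(proteomes, small_hits)
    net = gene_sharing_network(proteomes, clusters, score_min=0.0)
    within, between = [], []
    for r in net.itertuples():
        same = truth.subgroup_of[r.source] == truth.subgroup_of[r.target]
        (within if same else between).append(r.score)
    assert min(within) > (max(between) if between else 0.0)


def test_no_shared_clusters_no_edge():
    clusters = taxonomy.MclResult(
        clusters=[{"gA_ORF1"}, {"gB_ORF1"}], inflation=2.0, iterations=1)
    proteomes = {"gA": {"gA_ORF1": "M"}, "gB": {"gB_ORF1": "M"}}
    net = gene_sharing_network(proteomes, clusters)
    assert net.empty


# ---------------------------------------------------------------------------
# subgroup delineation
# ---------------------------------------------------------------------------

def _stats_df(rows):
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "aai",
                                       "rbh_count", "shared_frac"])


def test_all_high_aai_one_subgroup():
    rows = [(a, b, 100.0, 10, 1.0) for a, b in
            [("x", "y"), ("x", "z"), ("y", "z")]]
    sg = delineate_subgroups(_stats_df(rows), ["x", "y", "z"])
    assert set(sg.label_of.values()) == {"I"}


def test_all_low_aai_all_singletons():
    rows = [(a, b, 30.0, 2, 0.2) for a, b in
            [("x", "y"), ("x", "z"), ("y", "z")]]
    sg = delineate_subgroups(_stats_df(rows), ["x", "y", "z"])
    assert sorted(sg.label_of.values()) == ["singleton-1", "singleton-2",
                                            "singleton-3"]


def test_subgroup_labels_by_size_then_id():
    rows = [("a", "b", 90.0, 10, 0.9), ("c", "d", 90.0, 10, 0.9),
            ("c", "e", 90.0, 10, 0.9), ("d", "e", 90.0, 10, 0.9),
            ("a", "c", 10.0, 1, 0.1), ("b", "f", 10.0, 1, 0.1)]
    sg = delineate_subgroups(_stats_df(rows), list("abcdef"))
    assert sg.label_of["c"] == "I"          # size-3 component
    assert sg.label_of["a"] == "II"
    assert sg.label_of["f"] == "singleton-1"


def test_delineation_input_order_invariant(small_family, small_hits):
    _g, proteomes, truth = small_family
    stats = pairwise_stats(proteomes, small_hits)
    gids = sorted(proteomes)
    fwd = delineate_subgroups(stats, gids)
    rev = delineate_subgroups(stats.iloc[::-1].reset_index(drop=True),
                              gids[::-1])
    assert fwd.label_of == rev.label_of


def test_family_partition_recovered_ari_1(small_family, small_hits):
    from sklearn.metrics import adjusted_rand_score

    _g, proteomes, truth = small_family
    stats = pairwise_stats(proteomes, small_hits)
    gids = sorted(proteomes)
    sg = delineate_subgroups(stats, gids)
    ari = adjusted_rand_score([truth.subgroup_of[g] for g in gids],
                              [sg.label_of[g] for g in gids])
    assert ari == 1.0


# ---------------------------------------------------------------------------
# proteomic distance
# ---------------------------------------------------------------------------

def test_distance_self_zero(small_family, small_hits):
    _g, proteomes, _t = small_family
    g = sorted(proteomes)[0]
    assert proteomic_distance(g, g, proteomes, small_hits) == 0.0


def test_distance_no_hits_one(random_pair):
    hits = all_vs_all(random_pair)
    assert proteomic_distance("gA", "gB", random_pair, hits) == 1.0


def test_distance_orders_subgroups(small_family, small_hits):
    _g, proteomes, truth = small_family
    gids = sorted(proteomes)
    within, between = [], []
    for i, a in enumerate(gids):
        for b in gids[i + 1:]:
            d = proteomic_distance(a, b, proteomes, small_hits)
            same = truth.subgroup_of[a] == truth.subgroup_of[b]
            (within if same else between).append(d)
    assert max(within) < min(between)
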