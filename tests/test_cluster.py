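import pytest

from phamily.cluster import completeness_filter, greedy_derep, mcl
from phamily.seqio import GenomeRecord

from _oracles import reference_mcl


def _mut(rng, seq, frac):
    s = list(seq)
    for i in rng.choice(len(s), int(frac * len(s)), replace=False):
        s[i] = str(rng.choice([c for c in "ACGT" if c != s[i]]))
    return "".join(s)


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------

def test_completeness_boundaries():
    gs = [GenomeRecord("full", "A" * 1000), GenomeRecord("half", "A" * 500),
          GenomeRecord("frag", "A" * 300)]
    kept, report = completeness_filter(gs, expected_len=1000)
    names = {g.id for g in kept}
    assert names == {"full", "half"}  # drop condition is strictly below 50%
    rep = report.set_index("genome")
    assert rep.loc["full"].completeness == 1.0
    assert rep.loc["half"].completeness == 0.5
    assert not rep.loc["frag"].retained


def test_completeness_auto_requires_trusted():
    g = [GenomeRecord("a", "A" * 100)]
    with pytest.raises(ValueError):
        completeness_filter(g, expected_len="auto")
    kept, _rep = completeness_filter(g, expected_len="auto", trusted=g)
    assert kept == g


# ---------------------------------------------------------------------------
# greedy dereplication
# ---------------------------------------------------------------------------

def test_derep_exact_duplicates(rng):
    seq = "".join(rng.choice(list("ACGT"), 3000))
    res = greedy_derep([GenomeRecord("a", seq), GenomeRecord("b", seq)])
    assert res.centroids == ["a"]
    assert res.member_of == {"a": "a", "b": "a"}


def test_derep_ninety_percent_pair_stays_split(rng):
    seq = "".join(rng.choice(list("ACGT"), 3000))
    res = greedy_derep([GenomeRecord("a", seq),
                        GenomeRecord("b", _mut(rng, seq, 0.10))])
    assert len(res.centroids) == 2


def test_derep_mutated_copies_collapse(rng):
    seq = "".join(rng.choice(list("ACGT"), 3000))
    gs = [GenomeRecord(f"g{i}", _mut(rng, seq, 0.02)) for i in range(10)]
    res = greedy_derep(gs)
    assert len(res.centroids) == 1
    assert (res.stats.identity >= 0.95).all()


def test_derep_idempotent(rng):
    seq = "".join(rng.choice(list("ACGT"), 3000))
    gs = [GenomeRecord(f"g{i}", _mut(rng, seq, 0.02)) for i in range(6)]
    gs += [GenomeRecord("other", "".join(rng.choice(list("ACGT"), 2500)))]
    first = greedy_derep(gs)
    centroids = [g for g in gs if g.id in first.centroids]
    again = greedy_derep(centroids)
    assert again.centroids == first.centroids


def test_derep_threshold_monotone(rng):
    seq = "".join(rng.choice(list("ACGT"), 3000))
    gs = [GenomeRecord(f"g{i}", _mut(rng, seq, 0.03 * i)) for i in range(5)]
    n_95 = len(greedy_derep(gs, id_min=0.95).centroids)
    n_90 = len(greedy_derep(gs, id_min=0.90).centroids)
    assert n_90 <= n_95


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def _clique(nodes, w=1.0):
    import itertools

    return [(u, v, w) for u, v in itertools.combinations(nodes, 2)]


def test_mcl_disjoint_cliques():
    edges = _clique("abcd") + _clique("wxyz")
    res = mcl(edges)
    assert sorted(map(sorted, res.clusters)) == [list("abcd"), list("wxyz")]


def test_mcl_single_edge():
    res = mcl([("A", "B", 1.0)])
    assert res.clusters == [{"A", "B"}]


def test_mcl_empty_graph():
    assert mcl([]).clusters == []


def test_mcl_barbell_matches_reference():
    edges = _clique("abcde", 1.0) + _clique("vwxyz", 1.0) + [("e", "v", 0.01)]
    ours = sorted(map(sorted, mcl(edges, inflation=2.0).clusters))
    ref = sorted(map(sorted, reference_mcl(edges, inflation=2.0)))
    assert ours == ref == [list("abcde"), list("vwxyz")]


def test_mcl_relabel_invariance():
    edges = _clique("abcde") + _clique("fgh") + [("e", "f", 0.05)]
    base = sorted(map(sorted, mcl(edges, inflation=2.0).clusters))
    mapping = {c: f"node_{ord(c)}" for c in "abcdefgh"}
    relabeled = [(mapping[u], mapping[v], w) for u, v, w in edges]
    got = sorted(map(sorted, mcl(relabeled, inflation=2.0).clusters))
    expect = sorted(sorted(mapping[c] for c in cl) for cl in base)
    assert got == expect


def test_mcl_negative_weight_rejected():
    with pytest.raises(ValueError):
        mcl([("a", "b", -1.0)])
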