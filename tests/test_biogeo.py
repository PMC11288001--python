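import numpy as np
import pandas as pd
import pytest
from phamily import syndata
from phamily.biogeo import (BiogeoError, env_correlate, group_compare,
                            mannwhitney_exact_or_asymptotic, recruit_reads,
                            rpkm)
from phamily.seqio import gc_content

from _oracles import mannwhitney_exact_enumeration


@pytest.fixture(scope="module")
def two_genomes(small_family):
    genomes, _p, _t = small_family
    return genomes[:2]


def test_errorfree_reads_all_recruited(two_genomes):
    ref = two_genomes[0]
    reads, _m, truth = syndata.simulate_viromes(
        [ref], n_samples=3, reads_per_sample=300, err_rate=0.0, seed=1)
    counts = recruit_reads(reads, [ref])
    assert int(counts.to_numpy().sum()) == 900


def test_heavily_mutated_reads_rejected(two_genomes, rng):
    ref = two_genomes[0]
    reads, _m, _t = syndata.simulate_viromes(
        [ref], n_samples=3, reads_per_sample=100, err_rate=0.10, seed=2)
    counts = recruit_reads(reads, [ref])
    # 10% substitution is far below the 95% identity gate
    assert counts.to_numpy().sum() < 15


def test_recruit_empty_refs_rejected():
    with pytest.raises(BiogeoError):
        recruit_reads({"S01": []}, [])


def test_recruit_tightening_gates_monotone(two_genomes):
    ref = two_genomes[0]
    reads, _m, _t = syndata.simulate_viromes(
        [ref], n_samples=3, reads_per_sample=200, err_rate=0.02, seed=3)
    base = recruit_reads(reads, [ref], id_min=0.90).to_numpy().sum()
    for kw in (dict(id_min=0.97), dict(aln_min=140), dict(readcov_min=0.99)):
        assert recruit_reads(reads, [ref], **{**dict(id_min=0.90), **kw}
                             ).to_numpy().sum() <= base


def test_rpkm_arithmetic():
    counts = pd.DataFrame({"S1": [100]}, index=["g"])
    out = rpkm(counts, {"g": 10_000}, totals=pd.Series({"S1": 1_000_000}))
    assert out.rpkm.loc["g", "S1"] == pytest.approx(10.0)


def test_rpkm_zero_counts_and_scale_invariance():
    counts = pd.DataFrame({"S1": [0, 300]}, index=["a", "b"])
    lengths = {"a": 5000, "b": 20_000}
    out1 = rpkm(counts, lengths)
    assert out1.rpkm.loc["a", "S1"] == 0.0
    out2 = rpkm(counts * 2, lengths)
    pd.testing.assert_frame_equal(out1.rpkm, out2.rpkm)


def test_rpkm_zero_total_warns():
    counts = pd.DataFrame({"S1": [0]}, index=["g"])
    with pytest.warns(UserWarning):
        out = rpkm(counts, {"g": 1000})
    assert (out.rpkm.to_numpy() == 0).all()


def test_rpkm_zero_length_rejected():
    counts = pd.DataFrame({"S1": [1]}, index=["g"])
    with pytest.raises(BiogeoError):
        rpkm(counts, {"g": 0})


# ---------------------------------------------------------------------------
# environmental statistics
# ---------------------------------------------------------------------------

def _abund(values, samples):
    counts = pd.DataFrame({s: [int(v)] for s, v in zip(samples, values)},
                          index=["g"])
    return rpkm(counts, {"g": 1000},
                totals=pd.Series({s: 10_000 for s in samples}))


def test_perfect_linear_fit():
    samples = [f"S{i}" for i in range(10)]
    lat = np.arange(10.0, 60.0, 5.0)
    meta = pd.DataFrame({"sample": samples, "latitude": lat,
                         "temperature": 28 - 0.4 * lat,
                         "salinity": np.full(10, 34.0)})
    ab = _abund(100 + 20 * lat, samples)
    out = env_correlate(ab, meta).set_index("variable")
    assert out.loc["latitude"].r == pytest.approx(1.0)
    assert out.loc["latitude"].p < 0.05


def test_constant_abundance_is_na():
    samples = [f"S{i}" for i in range(6)]
    meta = pd.DataFrame({"sample": samples,
                         "latitude": np.arange(6.0),
                         "temperature": np.arange(6.0)[::-1],
                         "salinity": np.full(6, 34.0)})
    ab = _abund([50] * 6, samples)
    out = env_correlate(ab, meta)
    assert out.p.isna().all()
    assert out.note.str.startswith("zero-variance").all()


def test_exact_permutation_p_small_n():
    samples = [f"S{i}" for i in range(6)]
    rng = np.random.default_rng(5)
    lat = np.arange(6.0)
    meta = pd.DataFrame({"sample": samples, "latitude": lat,
                         "temperature": 28 - lat,
                         "salinity": np.full(6, 34.0)})
    ab = _abund(rng.integers(10, 500, 6), samples)
    out = env_correlate(ab, meta).set_index("variable")
    p = out.loc["latitude"].p
    assert p * 720 == pytest.approx(round(p * 720))  # multiple of 1/6!


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mw_textbook_example():
    u, p, method = mannwhitney_exact_or_asymptotic(
        np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
    assert u == 0.0 and method == "exact"
    assert p == pytest.approx(0.1)


@pytest.mark.parametrize("m,n", [(3, 3), (4, 4), (5, 4), (6, 6), (2, 6)])
def test_mw_matches_enumeration(m, n, rng):
    x = rng.permutation(np.arange(1.0, m + n + 1.0))[:m]
    y = np.array([v for v in np.arange(1.0, m + n + 1.0) if v not in set(x)])
    u_ours, p_ours, method = mannwhitney_exact_or_asymptotic(x, y)
    u_ref, p_ref = mannwhitney_exact_enumeration(list(x), list(y))
    assert method == "exact"
    assert u_ours == u_ref
    assert p_ours == pytest.approx(p_ref)


def test_mw_identical_groups_p_near_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    _u, p, _m = mannwhitney_exact_or_asymptotic(x, x + 0.001)
    assert p > 0.6


def test_group_compare_split_and_errors(small_family):
    genomes, _p, _t = small_family
    counts = pd.DataFrame({"S1": np.arange(len(genomes)) + 1},
                          index=[g.id for g in genomes])
    ab = rpkm(counts, {g.id: g.length_bp for g in genomes})
    gcs = {g.id: gc_content(g) for g in genomes}
    rep = group_compare(ab, gcs, split=0.45)
    assert rep["n_low_gc"] + rep["n_high_gc"] == len(genomes)
    with pytest.raises(BiogeoError):
        group_compare(ab, gcs, split=0.0)   # empty low group


def test_gc_exactly_at_split_joins_higher_group():
    counts = pd.DataFrame({"S1": [5, 10]}, index=["a", "b"])
    ab = rpkm(counts, {"a": 1000, "b": 1000})
    rep = group_compare(ab, {"a": 0.45, "b": 0.30}, split=0.45)
    assert rep["n_high_gc"] == 1 and rep["n_low_gc"] == 1
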