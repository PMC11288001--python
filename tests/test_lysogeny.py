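import numpy as np
import pytest

from phamily import syndata
from phamily.lysogeny import (LysogenyError, find_att, find_prophage,
                              junction_detect, verify_att)
from phamily.seqio import GenomeRecord, revcomp


@pytest.fixture(scope="module")
def lysogen_case(small_family):
    genomes, _p, _t = small_family
    lys, phage, host, feats, truth = syndata.generate_lysogen(
        genomes[0], seed=5, host_len=40_000)
    return dict(lys=lys, phage=phage, host=host,
                host_trnas=[f for f in feats if f.genome_id == host.id],
                phage_trnas=[f for f in feats if f.genome_id == phage.id],
                truth=truth, family=genomes)


def test_planted_core_rank1_exact(lysogen_case):
    c = lysogen_case
    sites = find_att(c["phage"], c["host"], c["host_trnas"],
                     c["phage_trnas"], min_len=12)
    top = sites[0]
    t = c["truth"]
    assert top.core == t.att_core
    assert (top.phage_start, top.phage_end) == t.attP
    assert (top.host_start, top.host_end) == t.attB
    assert top.overlaps_host_trna and top.near_phage_trna
    assert top.attL == t.attL and top.attR == t.attR


def test_att_sites_reverify_by_substring(lysogen_case):
    c = lysogen_case
    sites = find_att(c["phage"], c["host"], c["host_trnas"],
                     c["phage_trnas"], min_len=12)
    assert sites and all(verify_att(s, c["phage"], c["host"])
                         for s in sites)


def test_find_att_symmetric_roles(lysogen_case):
    c = lysogen_case
    fwd = find_att(c["phage"], c["host"], min_len=13, max_sites=1000)
    rev = find_att(c["host"], c["phage"], min_len=13, max_sites=1000)
    fwd_plus = {(s.core, s.phage_start, s.host_start) for s in fwd
                if s.strand == "+"}
    rev_plus = {(s.core, s.host_start, s.phage_start) for s in rev
                if s.strand == "+"}
    assert fwd_plus == rev_plus


def test_no_shared_substring_empty():
    # two short unrelated sequences cannot share a 12-mer on either strand
    rng_a = np.random.default_rng(101)
    a = GenomeRecord("a", "".join(rng_a.choice(list("ACGT"), 200)))
    b = GenomeRecord("b", "".join(rng_a.choice(list("ACGT"), 200)))
    assert find_att(a, b, min_len=12) == []


def test_reverse_strand_core_flagged(rng):
    core = "ACGGTTACCGGATCAA"  # 16 bp, not self-revcomp
    a = GenomeRecord("a", "".join(rng.choice(list("ACGT"), 3000)) + core
                     + "".join(rng.choice(list("ACGT"), 3000)))
    b = GenomeRecord("b", "".join(rng.choice(list("ACGT"), 3000))
                     + revcomp(core)
                     + "".join(rng.choice(list("ACGT"), 3000)))
    sites = find_att(a, b, min_len=12)
    top = [s for s in sites if s.core.find(core) >= 0
           or core.find(s.core) >= 0]
    assert top and top[0].strand == "-"


def test_min_len_noise_floor():
    a = GenomeRecord("a", "ACGT" * 100)
    with pytest.raises(LysogenyError):
        find_att(a, a, min_len=7)


# ---------------------------------------------------------------------------
# junction detection
# ---------------------------------------------------------------------------

def test_junctions_bracket_att_core(lysogen_case):
    c = lysogen_case
    reads, _m, _t = syndata.simulate_viromes(
        [c["lys"]], n_samples=3, reads_per_sample=1500, err_rate=0.002,
        seed=13)
    allreads = [r for s in sorted(reads) for r in reads[s]]
    clusters = junction_detect(allreads, c["phage"], c["host"])
    assert len(clusters) == 2
    t = c["truth"]
    got = sorted(cl.breakpoint for cl in clusters)
    assert abs(got[0] - t.attB[0]) <= 1
    assert abs(got[1] - t.attB[1]) <= 1
    assert {cl.side for cl in clusters} == {"host-phage", "phage-host"}


def test_pure_phage_reads_no_junctions(lysogen_case):
    c = lysogen_case
    reads, _m, _t = syndata.simulate_viromes(
        [c["phage"]], n_samples=3, reads_per_sample=400, err_rate=0.002,
        seed=14)
    allreads = [r for s in sorted(reads) for r in reads[s]]
    assert junction_detect(allreads, c["phage"], c["host"]) == []


def test_clip_min_precondition(lysogen_case):
    c = lysogen_case
    with pytest.raises(LysogenyError):
        junction_detect([("r1", "ACGTACGTAA")], c["phage"], c["host"],
                        clip_min=20)


# ---------------------------------------------------------------------------
# prophage detection
# ---------------------------------------------------------------------------

def test_prophage_boundaries_within_200(lysogen_case):
    c = lysogen_case
    calls = find_prophage([c["phage"]], [c["lys"]])
    assert len(calls) == 1
    t = c["truth"]
    assert abs(calls[0].start - t.integration_start) <= 200
    assert abs(calls[0].end - t.integration_end) <= 200
    assert calls[0].mean_identity >= 0.95
    assert calls[0].ref_coverage >= 0.5


def test_contig_without_prophage_no_call(lysogen_case):
    c = lysogen_case
    calls = find_prophage([c["phage"]], [c["host"]])
    assert calls == []


def test_diverged_prophage_below_gate_not_called(lysogen_case, rng):
    c = lysogen_case
    seq = list(c["lys"].seq)
    n_mut = int(0.10 * len(seq))
    for i in rng.choice(len(seq), n_mut, replace=False):
        seq[i] = str(rng.choice([x for x in "ACGT" if x != seq[i]]))
    diverged = GenomeRecord("diverged", "".join(seq))
    assert find_prophage([c["phage"]], [diverged]) == []


def test_short_contigs_skipped(lysogen_case):
    c = lysogen_case
    short = GenomeRecord("short", c["lys"].seq[:900])
    assert find_prophage([c["phage"]], [short]) == []
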