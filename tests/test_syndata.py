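import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phamily.align import global_protein
from phamily.seqio import gc_content
from phamily.syndata import (CORE_GENES, FamilySpec, SynDataError,
                             generate_family, generate_lysogen,
                             simulate_viromes)


def test_spec_validation():
    with pytest.raises(SynDataError):
        FamilySpec(within_divergence=0.3, between_divergence=0.4)
    with pytest.raises(SynDataError):
        FamilySpec(gc_targets=[0.2, 0.5, 0.5])
    with pytest.raises(SynDataError):
        FamilySpec(ancestor_gene_count=4)


def test_single_genome_no_divergence():
    spec = FamilySpec(n_subgroups=1, genomes_per_subgroup=1,
                      ancestor_gene_count=8, genome_len_bp=8000,
                      within_divergence=1.0, between_divergence=0.3, seed=1)
    genomes, proteomes, truth = generate_family(spec)
    assert len(genomes) == 1
    planted = truth.genes
    assert set(planted[planted.is_core].gene) == set(CORE_GENES)


def test_determinism_byte_identical():
    spec = dict(n_subgroups=2, genomes_per_subgroup=2,
                ancestor_gene_count=10, genome_len_bp=10_000, seed=11)
    a = generate_family(FamilySpec(**spec))
    b = generate_family(FamilySpec(**spec))
    assert all(x.seq == y.seq and x.id == y.id
               for x, y in zip(a[0], b[0]))
    pd.testing.assert_frame_equal(a[2].genes, b[2].genes)


def test_realized_divergence_measured_by_aligner(small_family):
    """Within/between identity lands in the +-0.05 band, measured by the
    pairwise aligner on core genes (the generator's own bookkeeping is not
    trusted here)."""
    genomes, _p, truth = small_family
    within, between = [], []
    genes = truth.genes
    for gene in ("TerL", "capsid"):
        sub = genes[genes.gene == gene].set_index("genome").protein
        ids = list(sub.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ident = global_protein(sub[ids[i]], sub[ids[j]]).identity
                same = (truth.subgroup_of[ids[i]]
                        == truth.subgroup_of[ids[j]])
                (within if same else between).append(ident)
    assert 0.70 <= np.mean(within) <= 0.80
    assert 0.30 <= np.mean(between) <= 0.40


def test_gc_targets_hit(small_family):
    genomes, _p, truth = small_family
    spec = truth.spec
    by_sg = {}
    for g in genomes:
        by_sg.setdefault(truth.subgroup_of[g.id], []).append(gc_content(g))
    for sg, target in zip(sorted(by_sg), spec.gc_targets):
        for gc in by_sg[sg]:
            assert abs(gc - target) <= 0.03


def test_only_core_genes_universal(small_family):
    genomes, _p, truth = small_family
    n = len(genomes)
    counts = truth.genes.groupby("gene").genome.nunique()
    universal = set(counts[counts == n].index)
    assert universal == set(CORE_GENES)


def test_truth_serialization_roundtrip(small_family, tmp_path):
    _g, _p, truth = small_family
    truth.to_dir(tmp_path)
    assert (tmp_path / "truth_subgroups.tsv").exists()
    genes = pd.read_csv(tmp_path / "truth_genes.tsv", sep="\t")
    assert len(genes) == len(truth.genes)


# ---------------------------------------------------------------------------
# lysogen
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def lysogen(small_family):
    genomes, _p, _t = small_family
    return generate_lysogen(genomes[0], seed=5, host_len=40_000)


def test_lysogen_length_conserved(lysogen):
    lys, phage, host, _f, _t = lysogen
    assert lys.length_bp == phage.length_bp + host.length_bp


def test_att_core_once_at_each_locus(lysogen):
    lys, phage, host, _f, t = lysogen
    core = t.att_core
    assert phage.seq.count(core) == 1
    assert host.seq.count(core) == 1
    assert lys.seq.count(core) == 2
    assert phage.seq[t.attP[0]:t.attP[1]] == core
    assert host.seq[t.attB[0]:t.attB[1]] == core
    assert lys.seq[t.attL[0]:t.attL[1]] == core
    assert lys.seq[t.attR[0]:t.attR[1]] == core


def test_attL_attR_flanks_contain_core_once(lysogen):
    lys, _p, _h, _f, t = lysogen
    left_flank = lys.seq[t.attL[0] - 200:t.attL[1] + 200]
    right_flank = lys.seq[t.attR[0] - 200:t.attR[1] + 200]
    assert left_flank.count(t.att_core) == 1
    assert right_flank.count(t.att_core) == 1


def test_lysogen_deterministic(small_family):
    genomes, _p, _t = small_family
    a = generate_lysogen(genomes[0], seed=5, host_len=40_000)
    b = generate_lysogen(genomes[0], seed=5, host_len=40_000)
    assert a[0].seq == b[0].seq


def test_att_len_validation(small_family):
    genomes, _p, _t = small_family
    with pytest.raises(SynDataError):
        generate_lysogen(genomes[0], att_len=6, seed=1)


# ---------------------------------------------------------------------------
# viromes
# ---------------------------------------------------------------------------

def test_errorfree_reads_are_substrings(small_family):
    genomes, _p, _t = small_family
    from phamily.seqio import revcomp

    reads, _m, _truth = simulate_viromes([genomes[0]], n_samples=3,
                                         reads_per_sample=50, err_rate=0.0,
                                         seed=2)
    for sample in reads.values():
        for _name, seq in sample:
            assert seq in genomes[0].seq or revcomp(seq) in genomes[0].seq


def test_null_model_equal_abundances(small_family):
    genomes, _p, _t = small_family
    _r, _m, truth = simulate_viromes(genomes[:3], n_samples=8,
                                     reads_per_sample=100, effect=0.0,
                                     noise_sd=0.0, seed=4,
                                     beta={g.id: 0.0 for g in genomes[:3]})
    ab = truth.abundance.to_numpy()
    assert np.allclose(ab, 1.0 / 3.0)


def test_latitude_gradient_sign_in_truth(small_family):
    genomes, _p, _t = small_family
    two = genomes[:2]
    beta = {two[0].id: +1.0, two[1].id: -1.0}
    _r, meta, truth = simulate_viromes(two, n_samples=12,
                                       reads_per_sample=100, seed=6,
                                       beta=beta)
    lat = meta.latitude.to_numpy()
    for g, b in beta.items():
        rho = stats.spearmanr(lat, truth.abundance.loc[g].to_numpy()).statistic
        assert np.sign(rho) == np.sign(b)


def test_temperature_anticorrelated_with_latitude(small_family):
    genomes, _p, _t = small_family
    _r, meta, _truth = simulate_viromes(genomes[:1], n_samples=12,
                                        reads_per_sample=10, seed=7)
    r = stats.pearsonr(meta.latitude, meta.temperature).statistic
    assert r < -0.9


def test_min_samples_validation(small_family):
    genomes, _p, _t = small_family
    with pytest.raises(SynDataError):
        simulate_viromes(genomes[:1], n_samples=2, reads_per_sample=10,
                         seed=1)
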