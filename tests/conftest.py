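import numpy as np
import pytest

from phamily import pipeline, syndata, taxonomy


SMALL_SPEC = dict(n_subgroups=2, genomes_per_subgroup=3,
                  ancestor_gene_count=14, genome_len_bp=14_000, seed=3)

MINI_CONFIG = {
    "seed": 5,
    "family": {"n_subgroups": 2, "genomes_per_subgroup": 3,
               "ancestor_gene_count": 14, "genome_len_bp": 14_000},
    "retrieval": {"n_decoys": 10},
    "phylo": {"bootstrap_n": 50},
    "lysogeny": {"junction_reads": 2000, "host_len": 40_000},
    "biogeo": {"n_samples": 4, "reads_per_sample": 1000},
}


@pytest.fixture(scope="session")
def small_family():
    """2 subgroups x 3 genomes, 14 ancestor genes (~14 kb)."""
    return syndata.generate_family(syndata.FamilySpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def small_hits(small_family):
    _genomes, proteomes, _truth = small_family
    return taxonomy.all_vs_all(proteomes)


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """A fast end-to-end pipeline run on the small family."""
    out = tmp_path_factory.mktemp("mini_run")
    cfg = {**MINI_CONFIG, "out_dir": str(out / "run")}
    return pipeline.run(cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The study-condition run: 3 subgroups x 5 genomes, 63 ancestor genes,
    ~57.7 kb, within/between identity 0.75/0.35, 80 decoys, seed 7."""
    out = tmp_path_factory.mktemp("default_run")
    return pipeline.run({"out_dir": str(out / "run")})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_627)
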