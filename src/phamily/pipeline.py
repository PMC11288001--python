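"""End-to-end orchestration with a single config and an auditable manifest.

``run(config)`` executes the stages in dependency order on a synthetic
family with planted truth:

    synth -> annotate -> retrieve -> derep -> classify -> phylo
          -> lysogeny -> biogeo

Every stage reads its inputs from, and writes its outputs to, the run
directory, so each is also runnable standalone on a prior run (that is what
the CLI subcommands do).  The manifest records the full config (every
threshold applied), a content hash of every output file, and the truth-based
recovery metrics, and contains no timestamps: a rerun with the same config
and seed is byte-identical, which is itself a tested property.

The hallmark seed alignments are built from one representative genome per
subgroup (a real mining run would supply curated seed alignments instead;
the retrieval math is identical).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeo, cluster, genecall, lysogeny, phylogeny, profile
from . import seqio, syndata, taxonomy
from .seqio import GenomeRecord
from .syndata import CORE_GENES, HALLMARKS, FamilySpec

STAGES = ("synth", "annotate", "retrieve", "derep", "classify", "phylo",
          "lysogeny", "biogeo")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "out_dir": "run",
    "stages": {s: True for s in STAGES},
    "family": {
        "n_subgroups": 3, "genomes_per_subgroup": 5,
        "ancestor_gene_count": 63, "genome_len_bp": 57_700,
        "within_divergence": 0.75, "between_divergence": 0.35,
        "gc_targets": None, "integrase_prob": 0.85,
        "accessory_loss_frac": 0.12, "accessory_gain": 3,
    },
    "retrieval": {"n_decoys": 80, "e_max": 1e-3, "bits_min": 50.0,
                  "id_min": 0.25, "cov_min": 0.80},
    "completeness": {"min_frac": 0.5},
    "derep": {"id_min": 0.95, "short_cov_min": 0.80},
    "classify": {"aai_min": 60.0, "shared_min": 0.5, "inflation": 2.0,
                 "ortho_inflation": 1.5},
    "phylo": {"bootstrap_n": 100, "gap_frac_max": 0.5, "min_genes_shared": 4},
    "lysogeny": {"att_len": 13, "min_len": 12, "clip_min": 20,
                 "junction_reads": 6000, "host_len": 100_000},
    "biogeo": {"n_samples": 6, "reads_per_sample": 2000, "err_rate": 0.005,
               "id_min": 0.95, "aln_min": 50, "readcov_min": 0.80,
               "gc_split": 0.45, "low_gc_boost": 1.0, "effect": 1.0},
}


class ConfigError(ValueError):
    pass


def make_config(overrides: dict | None = None) -> dict:
    """Defaults merged with overrides; unknown keys are rejected up front."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _merge(cfg, overrides, path="")
    return cfg


def _merge(base: dict, over: dict, path: str) -> None:
    for key, val in over.items():
        if key not in base:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            _merge(base[key], val, path=f"{path}{key}.")
        else:
            base[key] = val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """A run directory plus its accumulated metrics."""

    def __init__(self, config: dict):
        self.config = config
        self.dir = Path(config["out_dir"])
        self.dir.mkdir(parents=True, exist_ok=True)
        self.metrics: dict = {}
        mfile = self.dir / "metrics.json"
        if mfile.exists():
            self.metrics = json.loads(mfile.read_text())

    def path(self, *parts) -> Path:
        p = self.dir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def save_metrics(self) -> None:
        with open(self.dir / "metrics.json", "w") as fh:
            json.dump(self.metrics, fh, indent=1, sort_keys=True)

    def write_manifest(self) -> Path:
        outputs = {}
        for f in sorted(self.dir.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                outputs[str(f.relative_to(self.dir))] = _sha256(f)
        manifest = {"config": self.config, "outputs": outputs,
                    "metrics": self.metrics}
        path = self.dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synth(run: Run) -> None:
    cfg = run.config
    spec = FamilySpec(seed=cfg["seed"], **cfg["family"])
    genomes, proteomes, truth = syndata.generate_family(spec)
    decoys = syndata.generate_decoys(n=cfg["retrieval"]["n_decoys"],
                                     seed=cfg["seed"] + 1)
    seqio.write_fasta(genomes, run.path("synth", "family.fna"))
    seqio.write_fasta(decoys, run.path("synth", "decoys.fna"))
    flat = {pid: seq for prots in proteomes.values()
            for pid, seq in prots.items()}
    seqio.write_fasta(flat, run.path("synth", "family_planted.faa"))
    truth.to_dir(run.path("synth", "truth"))
    run.metrics["synth"] = {
        "n_family": len(genomes), "n_decoys": len(decoys),
        "mean_len_kb": round(float(np.mean([g.length_bp for g in genomes]))
                             / 1000, 1),
    }


def _load_family(run: Run) -> list[GenomeRecord]:
    return seqio.read_fasta(run.path("synth", "family.fna"))


def _load_truth_subgroups(run: Run) -> dict[str, str]:
    df = seqio.read_tsv(run.path("synth", "truth", "truth_subgroups.tsv"))
    return dict(zip(df.genome, df.subgroup))


def _load_truth_genes(run: Run) -> pd.DataFrame:
    return seqio.read_tsv(run.path("synth", "truth", "truth_genes.tsv"))


def stage_annotate(run: Run) -> None:
    """Six-frame ORF calls (nested-pruned) for family + decoy contigs."""
    contigs = _load_family(run) + seqio.read_fasta(
        run.path("synth", "decoys.fna"))
    feats = []
    prots: dict[str, str] = {}
    n_calls = 0
    for g in contigs:
        calls = genecall.call_orfs(g, prune_nested=True)
        n_calls += len(calls)
        feats.extend(genecall.calls_to_features(calls))
        prots.update(genecall.proteome(calls))
    seqio.write_gff(sorted(feats, key=lambda f: (f.genome_id, f.start)),
                    run.path("annotate", "orfs.gff"))
    seqio.write_fasta(prots, run.path("annotate", "proteins.faa"))
    run.metrics["annotate"] = {"n_contigs": len(contigs), "n_orfs": n_calls}


def _called_proteomes(run: Run) -> dict[str, dict[str, str]]:
    prots = seqio.read_protein_fasta(run.path("annotate", "proteins.faa"))
    out: dict[str, dict[str, str]] = {}
    for pid, seq in prots.items():
        genome = pid.rsplit("_ORF", 1)[0]
        out.setdefault(genome, {})[pid] = seq
    return out


def hallmark_seed_msas(run: Run) -> dict[str, dict[str, str]]:
    """Seed alignments: hallmark proteins of one genome per subgroup."""
    genes = _load_truth_genes(run)
    subgroups = _load_truth_subgroups(run)
    reps = {}
    for g, sg in sorted(subgroups.items()):
        reps.setdefault(sg, g)
    msas = {}
    for gene in HALLMARKS:
        sub = genes[genes.gene == gene]
        seqs = {f"{r.genome}|{gene}": r.protein for r in sub.itertuples()
                if r.genome in reps.values()}
        if len(seqs) >= 2:
            msas[gene] = phylogeny.center_star_msa(seqs, name=gene).rows
        else:  # single-subgroup family: duplicate the lone seed's genome mate
            sub2 = sub.head(2)
            seqs = {f"{r.genome}|{gene}": r.protein
                    for r in sub2.itertuples()}
            msas[gene] = phylogeny.center_star_msa(seqs, name=gene).rows
    return msas


def stage_retrieve(run: Run) -> None:
    cfg = run.config["retrieval"]
    proteomes = _called_proteomes(run)
    models = [profile.build_profile(msa, name)
              for name, msa in hallmark_seed_msas(run).items()]
    retained_all: set[str] = set()
    tables = []
    for name_model in models:
        for genome, prots in proteomes.items():
            hits = profile.search_profile(
                name_model, prots, e_max=cfg["e_max"],
                bits_min=cfg["bits_min"], id_min=cfg["id_min"],
                cov_min=cfg["cov_min"])
            for h in hits:
                h.contig_id = genome
            if hits:
                retained_all.add(genome)
            tables.append(pd.DataFrame(
                [{"contig": genome, "orf": h.orf_id, "profile": h.profile,
                  "bitscore": round(h.bitscore, 1),
                  "seed_identity": round(h.seed_identity, 4),
                  "coverage": round(h.coverage, 4), "evalue": h.evalue}
                 for h in hits]))
    table = pd.concat([t for t in tables if not t.empty], ignore_index=True) \
        if any(not t.empty for t in tables) else pd.DataFrame(
            columns=["contig", "orf", "profile", "bitscore", "seed_identity",
                     "coverage", "evalue"])
    table = table.sort_values(["contig", "profile", "orf"]).reset_index(
        drop=True)
    seqio.write_tsv(table, run.path("retrieve", "hallmark_hits.tsv"))
    retained = sorted(retained_all)
    (run.path("retrieve", "retained.txt")).write_text(
        "\n".join(retained) + "\n")
    truth_family = set(_load_truth_subgroups(run))
    tp = len(truth_family & retained_all)
    fp = len(retained_all - truth_family)
    fn = len(truth_family - retained_all)
    run.metrics["retrieve"] = {
        "n_retained": len(retained),
        "precision": tp / (tp + fp) if retained else 0.0,
        "recall": tp / (tp + fn) if truth_family else 0.0,
    }


def stage_derep(run: Run) -> None:
    cfg = run.config
    retained_ids = (run.path("retrieve", "retained.txt")
                    .read_text().split())
    contigs = {g.id: g for g in _load_family(run)
               + seqio.read_fasta(run.path("synth", "decoys.fna"))}
    retained = [contigs[i] for i in retained_ids if i in contigs]
    kept, report = cluster.completeness_filter(
        retained, expected_len="auto",
        min_frac=cfg["completeness"]["min_frac"], trusted=retained)
    seqio.write_tsv(report, run.path("derep", "completeness.tsv"))
    derep = cluster.greedy_derep(kept, id_min=cfg["derep"]["id_min"],
                                 short_cov_min=cfg["derep"]["short_cov_min"])
    seqio.write_tsv(derep.stats, run.path("derep", "derep.tsv"))
    (run.path("derep", "centroids.txt")).write_text(
        "\n".join(derep.centroids) + "\n")
    run.metrics["derep"] = {"n_in": len(retained), "n_kept": len(kept),
                            "n_centroids": len(derep.centroids)}


def stage_classify(run: Run) -> None:
    cfg = run.config["classify"]
    centroids = (run.path("derep", "centroids.txt")).read_text().split()
    family_ids = sorted(set(centroids) & set(_load_truth_subgroups(run)))
    proteomes = {g: p for g, p in _called_proteomes(run).items()
                 if g in family_ids}
    hits = taxonomy.all_vs_all(proteomes)
    hits.to_csv(run.path("classify", "all_vs_all.tsv"), sep="\t",
                index=False, float_format="%.6g")
    groups = taxonomy.ortho_groups(proteomes, hits=hits,
                                   inflation=cfg["ortho_inflation"])
    rows = [{"group": g.group_id, "genome": gid, "protein": pid}
            for g in groups for gid, pid in g.members]
    seqio.write_tsv(pd.DataFrame(rows), run.path("classify", "orthogroups.tsv"))
    core = taxonomy.core_genes(groups, family_ids, 1.0, hits=hits)
    rows = [{"group": g.group_id, "genome": gid, "protein": pid}
            for g in core for gid, pid in g.members]
    seqio.write_tsv(pd.DataFrame(rows), run.path("classify", "coregenes.tsv"))
    stats = taxonomy.pairwise_stats(proteomes, hits)
    seqio.write_tsv(stats, run.path("classify", "pairwise_stats.tsv"))
    assign = taxonomy.delineate_subgroups(stats, family_ids,
                                          aai_min=cfg["aai_min"],
                                          shared_min=cfg["shared_min"])
    seqio.write_tsv(pd.DataFrame(
        [{"genome": g, "subgroup": s}
         for g, s in sorted(assign.label_of.items())]),
        run.path("classify", "subgroups.tsv"))
    pclusters = taxonomy.protein_clusters(proteomes, hits,
                                          inflation=cfg["inflation"])
    net = taxonomy.gene_sharing_network(proteomes, pclusters)
    seqio.write_tsv(net, run.path("classify", "network.tsv"))
    dmat = taxonomy.distance_matrix(proteomes, hits)
    dmat.to_csv(run.path("classify", "proteomic_distance.tsv"), sep="\t",
                float_format="%.6g")

    from sklearn.metrics import adjusted_rand_score

    truth_sub = _load_truth_subgroups(run)
    ari = adjusted_rand_score([truth_sub[g] for g in family_ids],
                              [assign.label_of[g] for g in family_ids])
    truth_pi = seqio.read_tsv(run.path("synth", "truth",
                                       "truth_pair_identity.tsv"))
    merged = stats.merge(truth_pi, on=["genome_a", "genome_b"])
    aai_err = (merged.aai - 100.0 * merged.identity).abs()
    run.metrics["classify"] = {
        "n_ortho_groups": len(groups),
        "n_core_groups": len(core),
        "subgroup_ari": float(ari),
        "aai_max_abs_err": float(aai_err.max()),
        "aai_mean_abs_err": float(aai_err.mean()),
        "n_network_edges": len(net),
    }


def stage_phylo(run: Run) -> None:
    cfg = run.config["phylo"]
    core_df = seqio.read_tsv(run.path("classify", "coregenes.tsv"))
    prots = seqio.read_protein_fasta(run.path("annotate", "proteins.faa"))
    genes = _load_truth_genes(run)
    # label each core group by the planted gene its proteins match, via
    # exact sequence lookup (falls back to group id)
    planted = {r.protein: r.gene for r in genes.itertuples()
               if r.gene in CORE_GENES}
    msas = []
    for group, sub in core_df.groupby("group"):
        seqs = {r.genome: prots[r.protein] for r in sub.itertuples()}
        names = {planted.get(s) for s in seqs.values()}
        names.discard(None)
        name = names.pop() if len(names) == 1 else group
        msas.append(phylogeny.center_star_msa(seqs, name=str(name)))
    concat, parts = phylogeny.trim_and_concat(
        msas, gap_frac_max=cfg["gap_frac_max"],
        min_genes_shared=min(cfg["min_genes_shared"], len(msas)))
    seqio.write_tsv(parts, run.path("phylo", "partitions.tsv"))
    tree = phylogeny.nj_tree(concat, bootstrap_n=cfg["bootstrap_n"],
                             seed=run.config["seed"])
    seqio.write_newick(tree, run.path("phylo", "core_genes.nwk"))
    truth_sub = _load_truth_subgroups(run)
    by_sg: dict[str, set] = {}
    present = tree.leaf_names()
    for g, sg in truth_sub.items():
        if g in present:
            by_sg.setdefault(sg, set()).add(g)
    mono = {sg: tree.is_monophyletic(m) for sg, m in by_sg.items()}
    supp = {sg: tree.clade_support(m) for sg, m in by_sg.items()
            if len(m) > 1 and mono[sg]}
    run.metrics["phylo"] = {
        "n_core_alignments": len(msas),
        "concat_columns": concat.ncol,
        "all_subgroups_monophyletic": bool(all(mono.values())),
        "min_subgroup_support": (min(supp.values()) if supp else None),
    }


def stage_lysogeny(run: Run) -> None:
    cfg = run.config["lysogeny"]
    seed = run.config["seed"]
    family = _load_family(run)
    lys, phage, host, feats, truth = syndata.generate_lysogen(
        family[0], att_len=cfg["att_len"], seed=seed + 2,
        host_len=cfg["host_len"])
    seqio.write_fasta([lys, phage, host], run.path("lysogeny", "genomes.fna"))
    seqio.write_gff(sorted(feats, key=lambda f: (f.genome_id, f.start)),
                    run.path("lysogeny", "features.gff"))
    host_trnas = [f for f in feats if f.genome_id == host.id]
    phage_trnas = [f for f in feats if f.genome_id == phage.id]
    sites = lysogeny.find_att(phage, host, host_trnas, phage_trnas,
                              min_len=cfg["min_len"])
    seqio.write_tsv(lysogeny.att_report(sites),
                    run.path("lysogeny", "att_sites.tsv"))
    rank1 = sites[0] if sites else None
    att_exact = bool(
        rank1 is not None and rank1.core == truth.att_core
        and (rank1.phage_start, rank1.phage_end) == truth.attP
        and (rank1.host_start, rank1.host_end) == truth.attB)
    reads, _m, _t = syndata.simulate_viromes(
        [lys], n_samples=3,
        reads_per_sample=cfg["junction_reads"] // 3,
        err_rate=0.002, seed=seed + 3)
    allreads = [r for s in sorted(reads) for r in reads[s]]
    clusters = lysogeny.junction_detect(allreads, phage, host,
                                        clip_min=cfg["clip_min"])
    bnd = sorted([truth.attB[0], truth.attB[1]])
    offsets = sorted(min(abs(c.breakpoint - b) for b in bnd)
                     for c in clusters) if clusters else []
    calls = lysogeny.find_prophage([phage], [lys])
    lysogeny.prophage_gff(calls, run.path("lysogeny", "prophages.gff"))
    pro_off = None
    if calls:
        pro_off = max(abs(calls[0].start - truth.integration_start),
                      abs(calls[0].end - truth.integration_end))
    run.metrics["lysogeny"] = {
        "att_rank1_exact": att_exact,
        "n_att_sites": len(sites),
        "n_junction_clusters": len(clusters),
        "junction_max_offset_bp": (max(offsets) if offsets else None),
        "prophage_boundary_offset_bp": pro_off,
    }


def stage_biogeo(run: Run) -> None:
    cfg = run.config["biogeo"]
    seed = run.config["seed"]
    family = _load_family(run)
    centroid_ids = (run.path("derep", "centroids.txt")).read_text().split() \
        if run.path("derep", "centroids.txt").exists() else None
    refs = [g for g in family
            if centroid_ids is None or g.id in centroid_ids]
    reads, meta, truth = syndata.simulate_viromes(
        refs, n_samples=cfg["n_samples"],
        reads_per_sample=cfg["reads_per_sample"],
        err_rate=cfg["err_rate"], effect=cfg["effect"],
        gc_split=cfg["gc_split"], low_gc_boost=cfg["low_gc_boost"],
        seed=seed + 4)
    for sample in sorted(reads):
        seqio.write_fastq(reads[sample],
                          run.path("biogeo", "reads", f"{sample}.fastq"))
    seqio.write_tsv(meta, run.path("biogeo", "samples.tsv"))
    counts = biogeo.recruit_reads(reads, refs, id_min=cfg["id_min"],
                                  aln_min=cfg["aln_min"],
                                  readcov_min=cfg["readcov_min"])
    abund = biogeo.rpkm(counts, {g.id: g.length_bp for g in refs})
    abund.rpkm.round(4).to_csv(run.path("biogeo", "rpkm.tsv"), sep="\t")
    corr = biogeo.env_correlate(abund, meta)
    seqio.write_tsv(corr.round(6), run.path("biogeo", "env_correlation.tsv"))
    gcs = {g.id: seqio.gc_content(g) for g in refs}
    long = biogeo.abundance_long_table(abund, meta, gcs)
    seqio.write_tsv(long.round(6), run.path("biogeo", "abundance_long.tsv"))
    report = biogeo.group_compare(abund, gcs, split=cfg["gc_split"])
    # planted-truth recovery
    tc = truth.read_counts.loc[counts.index, counts.columns]
    denom = tc.to_numpy().sum()
    count_err = float(np.abs(counts.to_numpy() - tc.to_numpy()).sum() / denom)
    lat = corr[(corr.variable == "latitude") & corr.r.notna()]
    sign_ok = [bool((r.r > 0) == (truth.beta[r.genome] > 0))
               for r in lat.itertuples()]
    run.metrics["biogeo"] = {
        "recruit_rate": float(counts.to_numpy().sum()
                              / (cfg["n_samples"]
                                 * cfg["reads_per_sample"])),
        "count_abs_err_frac": count_err,
        "latitude_sign_match_frac": (float(np.mean(sign_ok))
                                     if sign_ok else None),
        "mannwhitney_p": report["p"],
        "mannwhitney_direction": report["direction"],
        "mannwhitney_method": report["method"],
    }


_STAGE_FN = {
    "synth": stage_synth, "annotate": stage_annotate,
    "retrieve": stage_retrieve, "derep": stage_derep,
    "classify": stage_classify, "phylo": stage_phylo,
    "lysogeny": stage_lysogeny, "biogeo": stage_biogeo,
}


def run(config: dict | None = None, **overrides) -> Run:
    """Execute the enabled stages in order; returns the Run with manifest.

    ``config`` may be a partial override dict (validated against the
    defaults).  Any stage error aborts the run, naming the stage.
    """
    cfg = make_config(config)
    if overrides:
        _merge(cfg, overrides, path="")
    r = Run(cfg)
    for stage in STAGES:
        if not cfg["stages"].get(stage, False):
            continue
        try:
            _STAGE_FN[stage](r)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        r.save_metrics()
    r.write_manifest()
    return r
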