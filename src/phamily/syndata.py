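"""Synthetic phage family, lysogens, and virome read sets with planted truth.

The generator emulates the statistical structure of a marine phage family of
~50-70 kb genomes split into genus-level subgroups:

* a star-within-star divergence model: one family ancestor proteome, one
  mutated ancestor per subgroup, one mutated leaf per genome, with per-branch
  substitution rates solved analytically so that realized mean amino-acid
  identity hits the within/between-subgroup targets;
* six core genes present in every genome (portal, TerL, capsid, PD-(D/E)XK
  nuclease, AAA ATPase, Prim-Pol) plus accessory gain/loss per subgroup and
  an optional integrase;
* per-subgroup G+C targets reached by biasing synonymous codon choice during
  back-translation (intergenic spacers are composition-matched);
* Campbell-style lysogen construction sharing a short att core with a host
  tRNA locus;
* virome read sets whose genome abundances follow a latitude gradient with
  the sign of the effect tied to genome G+C, temperature anti-correlated
  with latitude by construction.

Every random draw comes from one ``numpy.random.default_rng(seed)`` stream
(PCG64), so regeneration under a fixed seed is byte-identical.

Intergenic spacers end with the 12-mer ``TTAATTAATTAA`` (its own reverse
complement, containing a stop codon in all six frames) placed immediately
before each start codon, so planted ORFs are exactly recoverable by a
deterministic six-frame caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import GenomeRecord, FeatureRecord, gc_content

CORE_GENES = ("portal", "TerL", "capsid", "PDDEXK", "AAA_ATPase", "PrimPol")
_CORE_LEN = {"portal": 420, "TerL": 450, "capsid": 350,
             "PDDEXK": 280, "AAA_ATPase": 300, "PrimPol": 480}
HALLMARKS = ("TerL", "capsid", "PrimPol")

STOP_CASSETTE = "TTAATTAATTAA"  # stop codons in all six frames; self-revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_M = AA20.index("M")


def _codon_tables():
    from Bio.Data import CodonTable

    fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


_CODONS_BY_AA = _codon_tables()
_CODON_GC = {c: c.count("G") + c.count("C") for cods in _CODONS_BY_AA.values()
             for c in cods}
for _stop in ("TAA", "TAG", "TGA"):
    _CODON_GC[_stop] = _stop.count("G") + _stop.count("C")


class SynDataError(ValueError):
    pass


@dataclass
class FamilySpec:
    """Study conditions for one synthetic family."""

    n_subgroups: int = 3
    genomes_per_subgroup: int = 5
    ancestor_gene_count: int = 63
    genome_len_bp: int = 57_700
    within_divergence: float = 0.75    # target mean aa identity within subgroup
    between_divergence: float = 0.35   # target identity between subgroups
    gc_targets: list[float] | None = None
    integrase_prob: float = 0.85
    accessory_loss_frac: float = 0.12
    accessory_gain: int = 3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_subgroups < 1 or self.genomes_per_subgroup < 1:
            raise SynDataError("need >=1 subgroup and >=1 genome per subgroup")
        if not (self.within_divergence > self.between_divergence):
            raise SynDataError("within_divergence must exceed between_divergence")
        if self.gc_targets is None:
            if self.n_subgroups == 1:
                self.gc_targets = [0.50]
            else:
                self.gc_targets = list(
                    np.round(np.linspace(0.38, 0.62, self.n_subgroups), 4))
        if len(self.gc_targets) != self.n_subgroups:
            raise SynDataError("gc_targets must have one entry per subgroup")
        for t in self.gc_targets:
            if not (0.35 <= t <= 0.66):
                raise SynDataError(
                    f"gc target {t} outside the family's observed range "
                    "[0.35, 0.66]")
        if self.ancestor_gene_count < len(CORE_GENES):
            raise SynDataError("ancestor_gene_count must cover the 6 core genes")


@dataclass
class PlantedTruth:
    """Complete ground truth for scoring every downstream stage."""

    subgroup_of: dict[str, str]
    genes: pd.DataFrame        # genome, gene, start, end, strand, is_core, protein
    pair_identity: pd.DataFrame  # genome_a, genome_b, identity, same_subgroup
    gc: dict[str, float]
    spec: FamilySpec

    def core_coords(self, genome_id: str) -> dict[str, tuple[int, int]]:
        sub = self.genes[(self.genes.genome == genome_id) & self.genes.is_core]
        return {r.gene: (int(r.start), int(r.end)) for r in sub.itertuples()}

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [{"genome": g, "subgroup": s} for g, s in self.subgroup_of.items()]
        ).to_csv(out / "truth_subgroups.tsv", sep="\t", index=False)
        self.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.pair_identity.to_csv(out / "truth_pair_identity.tsv", sep="\t",
                                  index=False)
        with open(out / "truth_gc.json", "w") as fh:
            json.dump(self.gc, fh, indent=1, sort_keys=True)
        with open(out / "spec.json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=1)


def _branch_rate(target_identity: float) -> float:
    """Per-branch substitution probability so two leaves of a star match
    ``target_identity`` of sites: (1-p)^2 + p^2/19 = target."""
    a = 1.0 + 1.0 / 19.0
    b = -2.0
    c = 1.0 - target_identity
    disc = b * b - 4 * a * c
    if disc < 0:
        raise SynDataError(f"infeasible identity target {target_identity}")
    return (-b - np.sqrt(disc)) / (2 * a)


def _mutate(rng: np.random.Generator, protein: np.ndarray,
            p: float) -> np.ndarray:
    """Substitute each site with probability p to a uniform different residue."""
    out = protein.copy()
    hit = rng.random(out.shape[0]) < p
    idx = np.nonzero(hit)[0]
    if idx.size:
        shift = rng.integers(1, 20, size=idx.size)
        out[idx] = (out[idx] + shift) % 20
    out[0] = _M  # the start residue is fixed (ATG start codon)
    return out


def _aa_string(code: np.ndarray) -> str:
    return "".join(AA20[i] for i in code)


def _solve_codon_bias(aa_counts: dict[str, int], fixed_gc: float,
                      fixed_len: int, flex_spacer_len: int,
                      target: float) -> float:
    """Find the codon-bias parameter eta so expected genome G+C hits target.

    Codon weights are exp(eta * gc_of_codon); spacer tails are drawn at the
    target composition and count as hitting it exactly.
    """

    def expected_gc(eta: float) -> float:
        gc = fixed_gc + flex_spacer_len * target
        total = fixed_len + flex_spacer_len
        for aa, cnt in aa_counts.items():
            cods = _CODONS_BY_AA[aa]
            w = np.exp(eta * np.array([_CODON_GC[c] for c in cods]))
            egc = float(np.sum(w * [_CODON_GC[c] for c in cods]) / w.sum())
            gc += cnt * egc
            total += cnt * 3
        return gc / total

    lo, hi = -8.0, 8.0
    flo, fhi = expected_gc(lo) - target, expected_gc(hi) - target
    if flo > 0 or fhi < 0:
        raise SynDataError(
            f"gc target {target} infeasible for this protein composition; "
            "relax gc_targets toward 0.5")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_gc(mid) - target <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _back_translate(rng: np.random.Generator, protein: str, eta: float) -> str:
    codons = ["ATG"]  # fixed start; planted proteins begin with M
    for aa in protein[1:]:
        cods = _CODONS_BY_AA[aa]
        w = np.exp(eta * np.array([_CODON_GC[c] for c in cods]))
        w = w / w.sum()
        codons.append(cods[int(rng.choice(len(cods), p=w))])
    stops = ["TAA", "TAG", "TGA"]
    w = np.exp(eta * np.array([_CODON_GC[c] for c in stops]))
    w = w / w.sum()
    codons.append(stops[int(rng.choice(3, p=w))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_family(spec: FamilySpec
                    ) -> tuple[list[GenomeRecord], dict[str, dict[str, str]],
                               PlantedTruth]:
    """Generate genomes, per-genome proteomes, and complete planted truth.

    Proteomes are ``{genome_id: {f"{genome_id}|{gene}": protein}}`` in gene
    order along the genome.
    """
    rng = np.random.default_rng(spec.seed)
    n_acc = spec.ancestor_gene_count - len(CORE_GENES)
    has_integrase_gene = n_acc >= 1
    acc_names = []
    if has_integrase_gene:
        acc_names.append("integrase")
    acc_names += [f"acc{i:03d}" for i in range(1, n_acc - len(acc_names) + 1)]

    # gene lengths (aa): fixed realistic core lengths; accessory drawn so the
    # genome lands near genome_len_bp
    overhead_per_gene = len(STOP_CASSETTE) + 18  # cassette + mean tail
    n_losable = max(0, n_acc - 1)  # integrase is never lost by drift
    n_loss_exp = int(round(spec.accessory_loss_frac * n_losable))
    n_eff = (spec.ancestor_gene_count - n_loss_exp + spec.accessory_gain)
    total_codons = (spec.genome_len_bp - n_eff * overhead_per_gene) // 3
    core_codons = sum(_CORE_LEN.values()) + 2 * len(CORE_GENES)
    n_acc_kept = max(1, n_acc - n_loss_exp)
    acc_mean = max(90, (total_codons - core_codons
                        - 252 * spec.accessory_gain) // n_acc_kept - 2)
    gene_len = dict(_CORE_LEN)
    if has_integrase_gene:
        gene_len["integrase"] = 380
    for name in acc_names:
        if name == "integrase":
            continue
        gene_len[name] = int(np.clip(rng.normal(acc_mean, 50), 80, 650))

    # family ancestor proteome; natural (BLOSUM-marginal) composition keeps
    # high-G+C back-translation targets feasible
    from .profile import background_frequencies

    bg = background_frequencies()
    order = list(CORE_GENES) + acc_names
    order = [order[i] for i in rng.permutation(len(order))]
    ancestor = {}
    for name in gene_len:
        seq = rng.choice(20, size=gene_len[name], p=bg)
        seq[0] = _M
        ancestor[name] = seq

    # branch rates
    g_rate = _branch_rate(spec.within_divergence)
    d_rate = _branch_rate(spec.between_divergence)
    if spec.n_subgroups > 1:
        f_rate = 1.0 - (1.0 - d_rate) / (1.0 - g_rate)
        if not (0.0 <= f_rate < 1.0):
            raise SynDataError("divergence targets imply an infeasible tree")
    else:
        f_rate = 0.0
    if spec.within_divergence >= 1.0:
        g_rate = 0.0

    genomes: list[GenomeRecord] = []
    proteomes: dict[str, dict[str, str]] = {}
    gene_rows = []
    subgroup_of: dict[str, str] = {}
    gc_real: dict[str, float] = {}
    leaf_proteins: dict[str, dict[str, np.ndarray]] = {}

    # ---- phase 1: decide gene content and protein sequences per genome ----
    orders: dict[str, list[str]] = {}
    gc_target_of: dict[str, float] = {}
    for si in range(spec.n_subgroups):
        sg_label = f"SG{si + 1}"
        sg_anc = {name: _mutate(rng, seq, f_rate)
                  for name, seq in ancestor.items()}
        # subgroup gene content: lose some accessories, gain exclusive ones
        losable = [n for n in acc_names if n != "integrase"]
        n_loss = int(round(spec.accessory_loss_frac * len(losable)))
        lost = set(rng.choice(losable, size=n_loss, replace=False)
                   ) if n_loss else set()
        sg_order = [n for n in order if n not in lost]
        for gi in range(spec.accessory_gain):
            name = f"{sg_label.lower()}_x{gi + 1}"
            length = int(np.clip(rng.normal(250, 40), 90, 500))
            gained = rng.choice(20, size=length, p=bg)
            gained[0] = _M
            sg_anc[name] = gained
            sg_order.insert(int(rng.integers(1, len(sg_order))), name)
        for gj in range(spec.genomes_per_subgroup):
            gid = f"{sg_label}_g{gj + 1}"
            subgroup_of[gid] = sg_label
            gc_target_of[gid] = spec.gc_targets[si]
            keep_integrase = (has_integrase_gene
                              and rng.random() < spec.integrase_prob)
            my_order = [n for n in sg_order
                        if n != "integrase" or keep_integrase]
            orders[gid] = my_order
            leaf_proteins[gid] = {name: _mutate(rng, sg_anc[name], g_rate)
                                  for name in my_order}

    # ---- phase 2: only the six planted core genes may be universal ----
    # (core genes are *defined* as the family-wide ortholog groups; any
    # accessory that drifted into universality is knocked out of one genome)
    gids_all = sorted(orders)
    if len(gids_all) > 1:
        for name in sorted({n for o in orders.values() for n in o}):
            if name in CORE_GENES:
                continue
            carriers = [g for g in gids_all if name in orders[g]]
            if len(carriers) == len(gids_all):
                victim = gids_all[int(rng.integers(0, len(gids_all)))]
                orders[victim] = [n for n in orders[victim] if n != name]
                del leaf_proteins[victim][name]

    # ---- phase 3: back-translate with per-genome codon bias and assemble ----
    for gid in sorted(orders, key=lambda g: gids_all.index(g)):
        my_order = orders[gid]
        prots = leaf_proteins[gid]
        gc_t = gc_target_of[gid]
        # codon bias solved per genome; stop codons are drawn with the same
        # bias and approximated as spacer-like in the expectation
        aa_counts: dict[str, int] = {}
        for name in my_order:
            for aa_i in prots[name][1:]:
                aa = AA20[aa_i]
                aa_counts[aa] = aa_counts.get(aa, 0) + 1
        n_genes = len(my_order)
        cassette_gc = STOP_CASSETTE.count("G") + STOP_CASSETTE.count("C")
        fixed_gc = n_genes * (1 + cassette_gc)  # ATG has 1 G
        fixed_len = n_genes * (3 + len(STOP_CASSETTE)) + n_genes * 3
        tail_lens = rng.integers(6, 31, size=n_genes + 1)
        flex_len = int(tail_lens.sum())
        eta = _solve_codon_bias(aa_counts, fixed_gc, fixed_len,
                                flex_len, gc_t)
        parts: list[str] = []
        pos = 0
        prot_map: dict[str, str] = {}
        for idx, name in enumerate(my_order):
            tail = _random_nt(rng, int(tail_lens[idx]), gc_t)
            parts.append(tail + STOP_CASSETTE)
            pos += len(tail) + len(STOP_CASSETTE)
            prot = prots[name]
            nt = _back_translate(rng, _aa_string(prot), eta)
            start = pos
            parts.append(nt)
            pos += len(nt)
            gene_rows.append({
                "genome": gid, "gene": name, "start": start, "end": pos,
                "strand": "+", "is_core": name in CORE_GENES,
                "protein": _aa_string(prot),
            })
            prot_map[f"{gid}|{name}"] = _aa_string(prot)
        parts.append(_random_nt(rng, int(tail_lens[-1]), gc_t))
        seq = "".join(parts)
        rec = GenomeRecord(id=gid, seq=seq, source="synthetic")
        genomes.append(rec)
        proteomes[gid] = prot_map
        gc_real[gid] = gc_content(rec)

    genes_df = pd.DataFrame(gene_rows)
    # realized pairwise mean identity over shared genes
    pid_rows = []
    gids = [g.id for g in genomes]
    for i in range(len(gids)):
        for j in range(i + 1, len(gids)):
            a, b = gids[i], gids[j]
            shared = set(leaf_proteins[a]) & set(leaf_proteins[b])
            idents = [
                float(np.mean(leaf_proteins[a][n] == leaf_proteins[b][n]))
                for n in sorted(shared)
            ]
            pid_rows.append({
                "genome_a": a, "genome_b": b,
                "identity": float(np.mean(idents)) if idents else np.nan,
                "same_subgroup": subgroup_of[a] == subgroup_of[b],
            })
    truth = PlantedTruth(
        subgroup_of=subgroup_of, genes=genes_df,
        pair_identity=pd.DataFrame(pid_rows), gc=gc_real, spec=spec)
    return genomes, proteomes, truth


def generate_decoys(n: int = 80, seed: int = 0, mean_len: int = 30_000,
                    gc: float = 0.5) -> list[GenomeRecord]:
    """Unrelated decoy contigs carrying their own random protein-coding genes.

    Decoys exercise the retrieval cascade's specificity: they have plausible
    ORF structure but no homology to the family.
    """
    from .profile import background_frequencies

    rng = np.random.default_rng(seed)
    bg = background_frequencies()
    decoys = []
    for i in range(n):
        length = int(np.clip(rng.normal(mean_len, mean_len * 0.25), 5_000,
                             mean_len * 2))
        n_genes = max(3, length // 950)
        parts = []
        used = 0
        for _ in range(n_genes):
            tail = _random_nt(rng, int(rng.integers(6, 31)), gc)
            prot = rng.choice(20, size=int(np.clip(rng.normal(280, 60), 80,
                                                   600)), p=bg)
            nt = _back_translate(rng, _aa_string(prot), 0.0)
            parts.append(tail + STOP_CASSETTE + nt)
            used += len(parts[-1])
            if used > length:
                break
        parts.append(_random_nt(rng, int(rng.integers(6, 31)), gc))
        decoys.append(GenomeRecord(id=f"decoy{i + 1:03d}", seq="".join(parts),
                                   source="host"))
    return decoys


# ---------------------------------------------------------------------------
# lysogen construction
# ---------------------------------------------------------------------------

@dataclass
class LysogenTruth:
    att_core: str
    attP: tuple[int, int]          # on the phage
    attB: tuple[int, int]          # on the (pre-integration) host
    attL: tuple[int, int]          # on the lysogen
    attR: tuple[int, int]          # on the lysogen
    host_trna: tuple[int, int]
    phage_trna: tuple[int, int]
    integration_start: int         # prophage span on the lysogen
    integration_end: int


def generate_lysogen(phage: GenomeRecord, host: GenomeRecord | None = None,
                     att_len: int = 13, seed: int = 0,
                     host_len: int = 100_000, host_gc: float = 0.56,
                     ) -> tuple[GenomeRecord, GenomeRecord, GenomeRecord,
                                list[FeatureRecord], LysogenTruth]:
    """Plant an att core and build the Campbell-integration lysogen.

    The core of ``att_len`` bp is planted once in the middle of a host tRNA
    and once downstream of a phage tRNA (both written into copies of the
    input sequences); the lysogen is host-left + core + phage-arc + core +
    host-right, so its length is exactly host + phage.  Returns
    (lysogen, phage-with-att, host-with-att, features, truth); the features
    carry the host and phage tRNA annotations.
    """
    if att_len < 8:
        raise SynDataError("att_len must be >= 8")
    rng = np.random.default_rng(seed)
    if host is None:
        host = GenomeRecord(id="hostA", seq=_random_nt(rng, host_len, host_gc),
                            source="host")
    host_seq = host.seq
    trna_len = 76
    t0 = len(host_seq) // 2 - trna_len // 2
    trna_seq = _random_nt(rng, trna_len, 0.55)
    host_seq = host_seq[:t0] + trna_seq + host_seq[t0 + trna_len:]

    phage_seq = phage.seq
    # phage tRNA planted at ~1/3 of the genome, core 20 bp downstream of it;
    # the phage carries its own (unrelated) tRNA — only the att core is
    # identical between the two genomes
    p_trna0 = len(phage_seq) // 3
    phage_trna_seq = _random_nt(rng, trna_len, 0.55)
    phage_seq = (phage_seq[:p_trna0] + phage_trna_seq
                 + phage_seq[p_trna0 + trna_len:])
    p_core0 = p_trna0 + trna_len + 20
    b_core0 = t0 + (trna_len - att_len) // 2  # middle of the host tRNA

    # the identical segment must be *exactly* att_len long: force the bases
    # flanking the planted core to differ between phage and host
    for h_i, p_i in ((b_core0 - 1, p_core0 - 1),
                     (b_core0 + att_len, p_core0 + att_len)):
        if host_seq[h_i] == phage_seq[p_i]:
            repl = next(c for c in "ACGT"
                        if c != phage_seq[p_i] and c != host_seq[h_i])
            host_seq = host_seq[:h_i] + repl + host_seq[h_i + 1:]

    core = None
    for _try in range(100):
        cand = _random_nt(rng, att_len, 0.5)
        h_test = host_seq[:b_core0] + cand + host_seq[b_core0 + att_len:]
        p_test = (phage_seq[:p_core0] + cand
                  + phage_seq[p_core0 + att_len:])
        from .seqio import revcomp

        if (_count_occurrences(h_test, cand) == 1
                and _count_occurrences(p_test, cand) == 1
                and _count_occurrences(h_test, revcomp(cand)) == 0
                and _count_occurrences(p_test, revcomp(cand)) == 0):
            core = cand
            host_seq, phage_seq = h_test, p_test
            break
    if core is None:
        raise SynDataError(
            "could not plant a unique att core in 100 attempts")

    host_rec = GenomeRecord(id=host.id, seq=host_seq, source="host")
    phage_rec = GenomeRecord(id=phage.id, seq=phage_seq, source=phage.source)
    lysogen_seq = (host_seq[:b_core0] + core
                   + phage_seq[p_core0 + att_len:] + phage_seq[:p_core0]
                   + core + host_seq[b_core0 + att_len:])
    assert len(lysogen_seq) == len(host_seq) + len(phage_seq)
    lysogen = GenomeRecord(id=f"{host.id}_lysogen", seq=lysogen_seq,
                           source="host")
    feats = [FeatureRecord(genome_id=host_rec.id, start=t0, end=t0 + trna_len,
                           strand="+", kind="tRNA", label="tRNA-Thr"),
             FeatureRecord(genome_id=phage_rec.id, start=p_trna0,
                           end=p_trna0 + trna_len, strand="+", kind="tRNA",
                           label="tRNA-Thr")]
    attL = (b_core0, b_core0 + att_len)
    attR = (b_core0 + phage_rec.length_bp, b_core0 + phage_rec.length_bp
            + att_len)
    truth = LysogenTruth(
        att_core=core, attP=(p_core0, p_core0 + att_len),
        attB=(b_core0, b_core0 + att_len), attL=attL, attR=attR,
        host_trna=(t0, t0 + trna_len),
        phage_trna=(p_trna0, p_trna0 + trna_len),
        integration_start=attL[0], integration_end=attR[1])
    return lysogen, phage_rec, host_rec, feats, truth


def _count_occurrences(s: str, sub: str) -> int:
    count = 0
    start = 0
    while True:
        i = s.find(sub, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


# ---------------------------------------------------------------------------
# virome simulation
# ---------------------------------------------------------------------------

@dataclass
class ViromeTruth:
    abundance: pd.DataFrame      # genomes x samples, true relative abundance
    metadata: pd.DataFrame       # sample, latitude, temperature, salinity, ...
    beta: dict[str, float]
    read_counts: pd.DataFrame    # genomes x samples planted read counts


def simulate_viromes(genomes: list[GenomeRecord], n_samples: int = 12,
                     reads_per_sample: int = 20_000, read_len: int = 150,
                     err_rate: float = 0.005, effect: float = 1.0,
                     gc_split: float = 0.45, low_gc_boost: float = 1.0,
                     noise_sd: float = 0.25, seed: int = 0,
                     beta: dict[str, float] | None = None,
                     ) -> tuple[dict[str, list[tuple[str, str]]],
                                pd.DataFrame, ViromeTruth]:
    """Simulate per-sample read sets along a latitude gradient.

    Expected relative abundance a_gs is proportional to
    exp(beta_g * z_s + eps) where z_s is standardized latitude and beta_g is
    +effect for genomes above the G+C split and -effect below it (overridable
    per genome via ``beta``).  ``low_gc_boost`` multiplies the abundance of
    low-G+C genomes uniformly across samples (the planted advantage studied
    by the high-vs-low G+C comparison).  Temperature is anti-correlated with
    latitude by construction; substitution errors only.

    Returns ({sample: [(read_name, seq), ...]}, metadata table, truth).
    """
    if n_samples < 3:
        raise SynDataError("need >= 3 samples for downstream correlation")
    if not genomes:
        raise SynDataError("no genomes supplied")
    rng = np.random.default_rng(seed)
    lat = np.linspace(5.0, 65.0, n_samples)
    z = (lat - lat.mean()) / lat.std()
    temp = 28.0 - 0.4 * lat + rng.normal(0, 0.8, n_samples)
    salinity = 33.5 + rng.normal(0, 1.2, n_samples)
    depth = np.full(n_samples, 5.0)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    meta = pd.DataFrame({
        "sample": samples, "latitude": np.round(lat, 3),
        "temperature": np.round(temp, 3), "salinity": np.round(salinity, 3),
        "depth": depth, "biome": ["marine"] * n_samples,
    })
    gcs = {g.id: gc_content(g) for g in genomes}
    if beta is None:
        beta = {g.id: (effect if gcs[g.id] > gc_split else -effect)
                for g in genomes}
    boost = {g.id: (low_gc_boost if gcs[g.id] <= gc_split else 1.0)
             for g in genomes}
    gids = [g.id for g in genomes]
    seq_arr = {g.id: np.frombuffer(g.seq.encode(), dtype=np.uint8)
               for g in genomes}
    lengths = np.array([g.length_bp for g in genomes], dtype=float)

    abund = np.zeros((len(genomes), n_samples))
    for gi, g in enumerate(genomes):
        eps = rng.normal(0, noise_sd, n_samples)
        abund[gi] = boost[g.id] * np.exp(beta[g.id] * z + eps)
    abund = abund / abund.sum(axis=0, keepdims=True)

    base_map = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    counts = np.zeros((len(genomes), n_samples), dtype=int)
    for sj, sample in enumerate(samples):
        p = abund[:, sj] * lengths
        p = p / p.sum()
        n_per = rng.multinomial(reads_per_sample, p)
        counts[:, sj] = n_per
        reads: list[tuple[str, str]] = []
        ridx = 0
        for gi, g in enumerate(genomes):
            arr = seq_arr[g.id]
            max_start = max(1, arr.shape[0] - read_len)
            starts = rng.integers(0, max_start, size=n_per[gi])
            strands = rng.random(n_per[gi]) < 0.5
            for t in range(n_per[gi]):
                sub = arr[starts[t]: starts[t] + read_len]
                read = sub.copy()
                if err_rate > 0:
                    errs = np.nonzero(rng.random(read.shape[0]) < err_rate)[0]
                    for e in errs:
                        choices = base_map[base_map != read[e]]
                        read[e] = choices[rng.integers(0, choices.shape[0])]
                seqstr = read.tobytes().decode()
                if strands[t]:
                    from .seqio import revcomp

                    seqstr = revcomp(seqstr)
                ridx += 1
                reads.append((f"{sample}_r{ridx}", seqstr))
        # shuffle read order so files are not grouped by genome
        perm = rng.permutation(len(reads))
        reads_by_sample[sample] = [reads[i] for i in perm]
    truth = ViromeTruth(
        abundance=pd.DataFrame(abund, index=gids, columns=samples),
        metadata=meta, beta=beta,
        read_counts=pd.DataFrame(counts, index=gids, columns=samples))
    return reads_by_sample, meta, truth
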