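# Methods

This note records the models, conventions, and numerical choices behind
`phamily`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not
demonstrate.

## Conventions shared by every stage

All internal coordinates are 0-based half-open on the forward strand;
every emitted text format (GFF3, BLAST-style tables, att reports, partition
files) is 1-based inclusive, converted in exactly one place
(`seqio.to_one_based`).  Nucleotide input is upper-cased, U→T, and anything
outside {A,C,G,T,N} is rejected rather than reinterpreted.

Alignment **identity** is matches / alignment columns with gap columns in
the denominator, and **coverage** is per-sequence (aligned residues / full
length) — the BLAST-report conventions, because every threshold in this
problem domain (25% identity, 80% coverage, 95% nucleotide identity,
"bitscore ≥ 50") descends from BLAST-style output.  Where a coverage
threshold does not name a side, the query side is used.  Bit-like scores
use the published ungapped BLOSUM62 constants (λ = 0.318, K = 0.13) and
e-values use search space |q|·|s|·n_subjects; both are stated
approximations whose only job is to give the literature's gates a stable,
reproducible meaning here.

## Alignment engine

Protein alignment is exact affine-gap dynamic programming (Smith–Waterman
and Needleman–Wunsch, gap of length L costs open + L·extend, BLAST
convention open 11 / extend 1), implemented as numba kernels with a
score-only prefilter pass for all-versus-all workloads; a pair is fully
tracebacked only if it reaches 25 bits, which is below the effective floor
of every downstream gate (the loosest gate, e ≤ 10⁻³, needs ≈30 bits even
for 30-residue proteins), so the prefilter cannot change any gated result.
Ties are resolved deterministically (first co-optimal end cell in
row-major order; aligned pair preferred over insertion over deletion;
fresh start preferred over a zero-scoring prefix).  The test suite checks
both kernels against an independently written full-matrix DP oracle on
hundreds of random pairs.

Nucleotide search (`nt_seed_extend`, the read mapper, the dereplicator,
the prophage finder) is exact k-mer seeding with **gapless** x-drop
extension — the classic ungapped-HSP regime.  This is a deliberate
simplification: every consumer applies a ≥ 95% identity gate, where
substitution-dominated alignment is the operative case, and the synthetic
read/genome generator is substitution-only by default (an indel knob
exists but is off).  Chained-segment statistics (dereplication coverage,
prophage coverage) are length-weighted over the chain.

## Hallmark profiles

A profile is a log-odds PSSM over the match columns (≤ 50% gaps) of a seed
alignment: score(col, a) = log₂(((count+1)/(n+20)) / bg(a)) with a +1
Laplace pseudocount against the BLOSUM62 marginal (Henikoff) background.
Searching is affine-gap local alignment of each candidate protein against
the PSSM; because PSSM scores are already log₂-odds, the raw score is the
bit-like score and e = |q|·L·2^(−bits).  A hit must clear all four gates
(e ≤ 10⁻³, bits ≥ 50, best-seed identity ≥ 25%, profile coverage ≥ 80%);
identity is measured against the nearest seed, the way one would verify a
profile hit by hand, not against the consensus.  This PSSM machinery is an
intentionally small stand-in for a Plan-7 profile HMM with the same
threshold semantics; it has no forward-algorithm posteriors or domain
envelopes.

## Gene calling

The caller is a deterministic six-frame scanner (table 11; starts ATG,
GTG, TTG; within a stop-bounded frame segment only the longest ORF is
kept; no partial calls at contig edges).  In pipeline mode it additionally
resolves heavy overlaps in two stages: calls nested ≥ 80% inside a call
≥ 1.25× longer are dropped, and among near-equal overlapping calls the
winner is chosen by a codon-usage score trained on the genome's own long
ORFs (mean per-codon log₂ of the genome's synonymous usage against uniform
synonymous choice).  The second stage matters specifically for high-G+C
genomes, where reverse-strand stop codons (AT-rich) are scarce and nearly
every real gene acquires a same-length antisense "twin" ORF; without the
codon-usage tie-break those twins displace real genes and bias AAI
downward by several points.  This is the package's miniature of the coding
statistics that production gene finders apply; it has no RBS model and is
not intended for real-genome annotation, where an external GFF can be
imported instead.

## Orthology, AAI, network, subgroups

All classification statistics share one all-versus-all hit table, so they
agree on what a hit is.  Ortholog groups are Markov clusters of the gated
similarity graph (e ≤ 10⁻³, identity ≥ 25%, query coverage ≥ 50%,
bitscore-weighted).  MCL inflation for orthology defaults to **1.5**: at
genus-level divergence (within-subgroup identity ~0.75 against
between-subgroup ~0.35) inflation 2.0 demonstrably shatters a single
ortholog's cross-subgroup clique into per-subgroup clusters, which is the
granularity orthology tools ship lower inflation to avoid.  The protein
clustering behind the gene-sharing network keeps inflation 2.0 with its
own harder gates (e < 10⁻⁵, bits ≥ 50).

AAI is the unweighted mean percent identity over reciprocal best hits;
shared-gene fraction divides the RBH count by the smaller gene count
(containment-friendly; the literature rarely states its denominator).
Subgroups are connected components of the genome graph gated at
AAI > 60% and shared fraction > 0.5, labeled by roman numerals in
decreasing size order; size-1 components are singletons.  Components are
used rather than a secondary clustering because at the divergences this
package targets the gated graph is essentially block-diagonal; the
gene-sharing network and the core-gene tree are emitted alongside as
independent lines of evidence.  The network edge score is the exact
hypergeometric tail (integer arithmetic up to N = 1000, scipy's survival
function beyond), penalized by the number of genome pairs tested.

The proteomic distance is 1 − sym(S_AB)/√(S_AA·S_BB) over gated best-hit
bitscore sums — a normalized proteome similarity used for the
whole-proteome dendrogram view.

## Phylogenomics

Center-star multiple alignment (center = minimum summed 1−identity;
"once a gap, always a gap" merging) feeds gap-column trimming (> 50% gaps
among rows that have the gene), fixed-order concatenation with recorded
partitions, pairwise-deletion p-distance (error if a pair shares < 10
columns), canonical neighbor joining (Studier–Keppler Q, deterministic tie
break, branch lengths clamped at 0), and a nonparametric column bootstrap
(default 100 replicates, bipartition frequencies × 100 on internal
nodes).  Center-star + NJ replaces a production MSA + ML pipeline; the
claim tested is clade recovery on data of known structure, not
branch-length fidelity.  NJ is verified to recover the generating topology
and path lengths exactly on random additive matrices.  Genomes present in
fewer than 4 of the 6 core-gene alignments are excluded (with a warning)
— the tolerance that lets half-complete genomes still be placed.

## Lysogeny

att discovery enumerates all maximal exact matches ≥ 12 bp between phage
and host on both strands (k-mer anchor, bidirectional exact extension).
Two design points: the minimum is set *below* the canonical 13 bp case so
a real site is found with margin, and host-tRNA overlap is a **ranking**
feature, not a filter — at these genome sizes dozens of ≥ 12 bp matches
occur by chance (expected ≈ 300 for 55 kb × 100 kb), and tRNA association
is what singles out the biological site, exactly as it does in practice.
attL/attR are predicted by Campbell arithmetic.  Junction detection maps
reads against phage+host jointly; a read with ≥ 20 clipped bases whose
clip maps to the other replicon at ≥ 95% identity votes for a breakpoint,
votes within ±3 bp are clustered, and the two resulting clusters bracket
the att core on the host map.  Prophage calls chain co-linear nucleotide
segments and gate on coverage of the *phage* query (a prophage is a whole
phage inside a long contig) at ≥ 50% and length-weighted identity ≥ 95%.

## Biogeography

Recruitment maps each read once: best gapless segment through the
reference k-mer index, gates ≥ 95% identity, ≥ 50 aligned bases, ≥ 80% of
the read; equal-best ties go to the lexicographically smallest reference
id (a deterministic alternative to discarding multi-mapped reads; a
discard mode exists).  RPKM divides by total *recruited* reads per sample
— the comparison is within a family-specific reference set, so the
family-internal denominator is the interpretable one; the raw library
size can be passed instead.  Correlations report Pearson r, Spearman ρ,
and the OLS slope with a two-sided p (exact permutation p when n ≤ 8);
no multiple-testing correction is applied to the headline values, but a
Benjamini–Hochberg column is emitted alongside.  The high- vs low-G+C
contrast (split at 45% G+C, a genome exactly at the split joins the higher
group) is a two-sided Mann–Whitney U, exact when both groups are ≤ 8
without cross-group ties, otherwise the tie-corrected normal
approximation.

## The synthetic generator and what passing means

The generator emulates a marine phage family as a star-within-star
divergence process: one ancestor proteome (BLOSUM-marginal amino-acid
composition), one mutated ancestor per subgroup, one mutated leaf per
genome.  Per-branch substitution probabilities are solved analytically
from the identity targets ((1−p)² + p²/19 = target, branches composed
multiplicatively), so realized mean pairwise identity lands within the
stated ±0.05 band — verified by the aligner, not by the generator's own
bookkeeping.  Back-translation hits per-subgroup G+C targets (±0.03) by
biasing synonymous codon choice, with the bias parameter solved by
bisection per genome; intergenic spacers are composition-matched and end
in a 12-mer stop cassette (stops in all six frames, its own reverse
complement) placed immediately before each start codon, which is what
makes planted ORFs exactly recoverable by a deterministic caller.  Subgroup
gene content drifts (12% accessory loss, 3 exclusive gains, optional
integrase), with the invariant that only the six core genes are universal
— core genes are *defined* as the family-wide groups, so an accessory that
drifts into universality is knocked out of one genome.  Lysogens are
Campbell integrations of a planted att core whose flanking bases are
forced to differ between phage and host (the identical segment is exactly
as long as planted).  Viromes follow a_gs ∝ exp(β_g z_s + ε) on
standardized latitude (northern-hemisphere stations, so temperature is
anti-correlated with latitude by construction), with β's sign tied to
genome G+C and an optional uniform low-G+C abundance boost; reads are
substitution-only at Q30.

Everything is drawn from a single `numpy.random.default_rng(seed)` (PCG64)
stream, so regeneration is byte-identical and the pipeline manifest (which
contains no timestamps) hashes identically across reruns.

What passing does **not** show: the generator has no indels, no assembly
artifacts or chimeras, no repeat families, no GC or amplification bias in
reads, no phylodynamics beyond the two-level star, and decoys are random
rather than genuinely homologous non-family phages.  Results on real
viromes therefore inherit only the logic and thresholds, not the measured
accuracies.

## Problem sizes used by tests and the acceptance script

The benchmark family is 3 subgroups × 5 genomes of ~57.7 kb (63 ancestor
genes) against 80 decoy contigs; the lysogeny benchmark uses a 100 kb host
and ~2 000 junction-spanning-capable reads; recruitment accuracy uses
2 genomes × 4 samples × 20 000 reads at 0.5% error; the gradient study
uses 60 small (6 kb) genomes — 30 low-G+C, 30 high-G+C with a ×3 planted
low-G+C advantage — across 12 samples × 20 000 reads; determinism is
demonstrated on a reduced configuration run twice.  These sizes were
chosen as the smallest at which each claim is statistically meaningful
(e.g., 30+30 genomes give the Mann–Whitney test the resolution for
p < 0.01; 20 000 reads put multinomial noise well under the 5% recruitment
tolerance).

## Known limitations

Single-CPU reference implementation; dense MCL (fine to a few thousand
proteins); no translated search; the completeness filter is a length
proxy, not a trained estimator; the gene caller is not a real-genome
annotator; e-values are Karlin–Altschul approximations with fixed
constants.  Each of these is behind a module boundary where a heavier tool
could be substituted without touching the rest of the pipeline.
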