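# Methods

## Scope and model

`tpsmine` implements a structure-first genome-mining procedure for
non-canonical terpene synthases (TPSs). Its premise: TPS function is
conserved at the fold level even when the primary sequence has diverged
beyond recognition, and TPS genes tend to sit near the *E*-isoprenyl
diphosphate synthase (E-IDS) that makes their substrate. The pipeline
therefore intersects four weak signals — genomic proximity to an E-IDS
anchor, absence of functional annotation, fold similarity to reference
class I/IB/IC TPS structures, and absence of sequence similarity to known
TPSs — each of which is cheap and none of which is sufficient alone.

## Coordinates and gene order

Gene coordinates are 0-based half-open internally; GenBank and GFF3 readers
convert at the boundary. Gene order (`rank`) sorts by start coordinate
within a contig, ignoring strand: the neighborhood window counts *genes*,
not base pairs, and only protein-coding, non-pseudo features participate.
Translation uses NCBI table 11 by default (bacterial genomes), with
alternative initiators forced to Met at position 0, ambiguous codons to X,
and a terminal stop dropped. Fuzzy coordinates are truncated with a warning;
trans-spliced CDS are skipped, not fatal.

## Alignment statistics

Local alignment is exact Gotoh dynamic programming (no seeding, no
composition statistics); candidate sets are small enough that correctness
beats speed, and the inner loops are numba-compiled. A gap of length L costs
`gap_open + L·gap_extend` (11 + L with the defaults, i.e. a length-1 gap
costs 12, the BLAST convention). Among co-optimal alignments the traceback
prefers matches over gaps and the earliest endpoint in row-major order,
making results deterministic; the exhaustive-enumeration oracle in the test
suite checks scores, which are tie-independent.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with the standard
gapped BLOSUM62 constants λ = 0.267 nats, K = 0.041. X scores 0 against
everything including X (neutral ambiguity; BLOSUM62's mild X penalties are
overridden). No effective-length (edge) correction is applied — short-query
E-values are slightly conservative in m·n and users who care can tighten
thresholds instead. Database searches use the total residue count of the
database as n, one search space per query. The exclusion step against known
TPS sequences has no published cutoff; it defaults to the same 10⁻⁵ used for
anchors and homologs and is configurable.

## Structure comparison

Comparison is Cα-only: predicted models carry per-residue pLDDT (read from
the B-factor column), side chains add noise, and fold-level screening does
not need them. Models are trimmed at pLDDT ≥ 70 (a conventional "confident"
bound; configurable), references are used as-is.

Kabsch superposition is SVD-based with the smallest singular direction
sign-corrected, so rotations are always proper (det +1); mirror-image decoys
cannot superpose exactly. TM-score uses the standard length-dependent scale
d₀(L) = 1.24(L−15)^⅓ − 1.8 Å, clamped to 0.5 Å for L ≤ 21, normalized by the
*reference* length, and is maximized over superpositions fit on the subset
of pairs currently within d₀ (iterate, keep the best score seen).

The sequence-independent aligner seeds from gapless threadings at stride-5
offsets plus an N-terminal 30-mer, then iterates {Kabsch fit → similarity
S_ij = 1/(1+(d_ij/d₀)²) → global DP, gap penalty −0.6, free end gaps} until
the pair set repeats or 30 rounds. Free end gaps depart from a strictly
global DP: terminal-extension penalties would bias against the
domain-vs-full-length comparisons the screen exists for. The reported RMSD
is over the final aligned pair set (how domain-vs-domain RMSDs are
conventionally quoted), so it is not comparable across tools that report
all-residue RMSD. TM ≥ 0.5, the conventional same-fold criterion, is the
screen threshold; the source screen named no tool or cutoff, so both are
explicit configuration.

## Typing, motifs, conservation

Types are connected components of the graph with edges where the pairwise
E-value (minimum of the two query/subject directions — conservative merging)
is below 0.1. Single linkage is the weakest assumption consistent with
"grouping by similarity"; lowering the threshold provably only refines the
partition. Cluster labels order by size, then smallest member.

"Sterically close" to the active site is implemented as Cα–Cα distance
≤ 5.0 Å (closed bound) from any reference catalytic residue after
superposition — an approximation of side-chain contact range chosen because
no published cutoff or atom selection exists; it is a config value. Note
that chain neighbors of a catalytic-adjacent residue are themselves within
3.8 Å, so proximal sets are contiguous stretches more often than the curated
handfuls a human would quote. Motif strings merge residues whose numbers
differ by ≤ max_gap+1 (default 3), rendering unlisted interior positions as
X; `{338:R, 341:K, 342:D}` → `RXXKD`.

Conservation uses a star MSA: homologs pairwise-aligned to the anchor and
projected onto anchor columns (insertions relative to the anchor are
invisible by construction — adequate for per-anchor-position logos, not a
general MSA). Information content is log₂20 − H over non-gap, non-X symbols,
no small-sample correction, pseudocount 0 by default; heights are
frequency × IC. Alternation groups like `(N/D)` appear only at the
conservation-report stage, when a column's top letter falls below 80%
frequency but the top two jointly reach it.

## Phylogeny

Distances are 1 − identity of the optimal local alignment (identity over
aligned pairs, gaps excluded), clamped to [0,1], with an optional Kimura
correction −ln(1 − p − p²/5); no multiple-hit correction by default since
the source tree's method is unstated and the simplest distance is the most
transparent default. Neighbor joining is the standard Q-matrix scheme with
ties broken by the lexicographically smallest name pair and negative branch
lengths clamped to 0 with the deficit moved to the sibling; the final three
nodes join at a trifurcating root. On additive matrices this recovers the
generating topology and branch lengths exactly (tested to 1e-9). No
bootstrap support is computed.

## Synthetic fixtures

The generator emulates the mining setting, not biology. Structures are
ideal Cα geometry: antiparallel helical bundles (rise 1.5 Å, 100°/residue,
helix radius 2.3 Å, axes on an 8 Å circle, 4-residue loops) and extended
zig-zag chains as fold-mismatch decoys. `perturb_structure` adds isotropic
Gaussian noise plus a random proper rigid transform, so superposed RMSD
concentrates at σ√3. Protein mutation substitutes a Bernoulli(1−identity)
fraction of positions with BLOSUM-positive replacements. Sequence and
structure are independent except where similarity is planted — the pipeline
never predicts structure, so coupling them would add nothing.

A default fixture genome has one contig of 30 genes with one anchor
(a 0.8-identity E-IDS copy) at the center, one candidate (0.75 identity to
a shared family parent, fold = class I reference + σ=1 Å noise) at offset
+3, one known-TPS decoy (0.7 identity to a known TPS, same fold — so only
the sequence filter can remove it) at offset −2, one hypothetical outside
the window at +13, and unrelated genes (every 5th one annotation-less with
an extended-chain structure, so the fold screen has real negatives).
Passing tests on these fixtures demonstrates that the filters compose and
discriminate as specified; they do not demonstrate performance on real
annotation noise, fragmented assemblies, or AlphaFold error modes, where
thresholds may need retuning.

## Problem sizes and numerics

Acceptance-level checks use 20 fixture genomes (30 genes each, ~150-residue
structure models), 100 brute-force alignment pairs of length ≤ 8, 100
Kabsch clouds against 10,000 random rigid placements each, and 50 random
5–12-taxon additive trees — sizes at which every oracle is exact or
Monte-Carlo-tight while the whole suite stays interactive. Determinism:
all randomness flows through seeded `numpy` generators; pipeline outputs
are fully ordered, so identical configs give byte-identical reports.
Degenerate inputs (empty sequences, <3 superposition points, <20-residue
models, <3 taxa, empty candidate lists) raise early with specific messages
rather than propagating NaNs.

## Known limitations

- E-value constants are not recomputed per scoring scheme; changing the
  matrix or gap costs without updating λ, K silently miscalibrates E.
- The structure aligner is rigid; hinge or domain-swapped similarity will
  underscore. It is also a local-optimum search over seeds, not a global
  optimizer, though the self/offset/decoy tests bound its behavior.
- The star MSA cannot represent anchor insertions; motif alternation groups
  are only as good as the homolog set.
- Homolog counts depend entirely on the supplied protein database; no
  remote fetching is performed.
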