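# tpsmine

Structural-model-based genome mining for **non-canonical terpene synthases
(TPSs)** — enzymes whose primary sequences show none of the canonical class I
motifs (DDXXD, NSE/DTE) and therefore evade BLAST- and HMM-based mining, but
whose predicted 3D folds still resemble class I TPSs.

The package is aimed at natural-product genome miners who have annotated
bacterial genomes plus per-protein structure models (e.g. AlphaFold DB files)
and want a ranked list of fold-similar, annotation-less candidates near the
genes that make the TPS substrate.

## The method

Four filters are chained over each genome:

1. **Anchor** — find *E*-isoprenyl diphosphate synthase (E-IDS) genes, which
   synthesize the prenyl diphosphate substrate, by local alignment against a
   reference E-IDS set (Karlin–Altschul E < 10⁻⁵).
2. **Window** — collect *hypothetical proteins* within ±k genes (default
   k = 10) of each anchor on the same contig.
3. **Fold screen** — superpose each candidate's Cα model (pLDDT-trimmed at 70)
   onto reference TPS structures with a sequence-independent iterative
   aligner; keep candidates with TM-score ≥ 0.5 against any reference, where

   TM = (1/L_ref) Σᵢ 1 / (1 + (dᵢ/d₀(L_ref))²),  d₀(L) = 1.24·(L−15)^⅓ − 1.8 Å.

4. **Sequence exclusion** — drop anything alignable to known TPS sequences
   (E < 10⁻⁵), so only *non-canonical* candidates remain.

Survivors are clustered into **types** (single-linkage on pairwise E < 0.1),
their residues sterically close (Cα–Cα ≤ 5 Å) to reference catalytic residues
are compressed into **motif strings** (discontinuous positions rendered with
X, e.g. `RXXKD`), conservation across homologs is summarized as per-column
information content IC = log₂20 − H in bits, and homolog sets get a
neighbor-joining tree from 1 − identity distances.

Local alignment is exact affine-gap Smith–Waterman (BLOSUM62, 11/1,
E = K·m·n·e^(−λS) with λ = 0.267, K = 0.041); superposition is Kabsch SVD
with reflection suppression. Every numerical core is tested against an
independent oracle (exhaustive alignment enumeration, Monte-Carlo rigid
transforms, additive-tree recovery).

## Worked example

The package ships a synthetic-fixture generator, so the whole workflow runs
without downloads. Each fixture genome plants an E-IDS anchor, one
fold-similar hypothetical candidate, a known-TPS-like decoy, and an
out-of-window hypothetical, with the truth recorded:

```bash
tpsmine fixtures make --out demo --seed 5 --n-genomes 2
tpsmine mine --config demo/mining.yaml --out demo/out
```

prints

```
2 candidate(s); stage counts: {'genomes': 2, 'anchors': 2, 'window': 40,
'hypothetical': 10, 'deduplicated': 10, 'with_model': 10,
'structure_pass': 4, 'after_known_tps': 2, 'final': 2}
```

Reading the counts: 2 anchors were found; 40 genes lie in their ±10 windows,
of which 10 are annotation-less; all 10 have structure models, 4 pass the
TM ≥ 0.5 fold screen (the two planted candidates and two planted decoys),
and the known-TPS exclusion leaves exactly the 2 planted candidates, grouped
into one type (`type-1` in `demo/out/types.tsv`). `demo/out/report.tsv`
carries per-candidate provenance (anchor E-value, best reference fold,
TM-score, RMSD, motif strings); `motifs.json` lists active-site-proximal
residues with distances. Single superpositions are available directly:

```bash
tpsmine align-structures demo/structures/synthgenome5000_00019.pdb \
    demo/kit/refs/classI_ref.pdb
# TM-score=0.8916 RMSD=1.649 A over 152 pairs (normalized by reference length 152)
```

`tpsmine census` counts homologs of each type in a protein FASTA and writes
neighbor-joining trees; `tpsmine logo` exports a position × letter
conservation matrix for logo plotters.

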