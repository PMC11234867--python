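"""Synthetic genomes, protein families, and Calpha structures with known truth.

Every pipeline stage is testable offline: a fixture genome plants a
mutated E-IDS anchor, a hypothetical-annotated candidate whose structure
is a noised copy of a reference terpene-synthase fold, a known-TPS-like
decoy that must fall to the sequence-exclusion filter, a hypothetical
outside the window, and unrelated genes with shuffled sequences and
extended-chain (non-globular) structures.  A truth table records every
planted role.

Structures are ideal Calpha geometry (helical bundles), not physically
relaxed: superposition scoring needs controllable geometry, not realism.
Sequences and structures are generated independently except where
identity or structural similarity is deliberately planted, since the
pipeline never predicts structure from sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from tpsmine.align import ALPHABET, blosum62
from tpsmine.genome_io import GeneRecord, GenomeAnnotation, write_genbank
from tpsmine.structure import StructureModel, write_pdb

_HELIX_RISE = 1.5        # A per residue along the helix axis
_HELIX_TURN = 100.0      # degrees per residue
_HELIX_RADIUS = 2.3      # A
_BUNDLE_RADIUS = 8.0     # A, helix axes on a circle
_LOOP_LEN = 4

_HELIX_AA = "ALEKDIRQMS"
_PRODUCTS = (
    "ABC transporter ATP-binding protein",
    "MFS transporter",
    "TetR family transcriptional regulator",
    "aldo/keto reductase",
    "two-component sensor histidine kinase",
    "acyl-CoA dehydrogenase",
    "ribosomal protein L33",
    "cytochrome P450",
)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = ALPHABET[:20]) -> str:
    body = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length - 1))
    return "M" + body


def make_helical_bundle(n_helices: int = 4, helix_len: int = 25, seed: int = 0,
                        model_id: str | None = None) -> StructureModel:
    """Ideal antiparallel helical bundle with 4-residue connecting loops.

    Residue count is n_helices * helix_len + (n_helices - 1) * 4; the
    sequence is helix-biased random, confidence is 90 throughout.
    """
    if n_helices < 2 or helix_len < 10:
        raise ValueError("need n_helices >= 2 and helix_len >= 10")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    height = (helix_len - 1) * _HELIX_RISE
    for h in range(n_helices):
        theta = 2.0 * math.pi * h / n_helices
        cx, cy = _BUNDLE_RADIUS * math.cos(theta), _BUNDLE_RADIUS * math.sin(theta)
        flip = h % 2 == 1
        helix = []
        for k in range(helix_len):
            ang = math.radians(_HELIX_TURN * k)
            x = cx + _HELIX_RADIUS * math.cos(ang)
            y = cy + _HELIX_RADIUS * math.sin(ang)
            z = (height - k * _HELIX_RISE) if flip else (k * _HELIX_RISE)
            helix.append(np.array([x, y, z]))
        if coords:
            prev = coords[-1]
            for k in range(1, _LOOP_LEN + 1):
                frac = k / (_LOOP_LEN + 1)
                coords.append(prev * (1 - frac) + helix[0] * frac)
        coords.extend(helix)
    n = len(coords)
    aa = "".join(_HELIX_AA[i] for i in rng.integers(0, len(_HELIX_AA), size=n))
    return StructureModel(
        model_id or f"bundle{n_helices}x{helix_len}s{seed}",
        np.arange(1, n + 1),
        aa,
        np.array(coords),
        np.full(n, 90.0),
    )


def make_extended_chain(n_residues: int = 150, seed: int = 0,
                        model_id: str | None = None) -> StructureModel:
    """Fully extended zig-zag chain (3.8 A Calpha spacing): a fold-mismatch decoy."""
    rng = np.random.default_rng(seed)
    xs = np.arange(n_residues) * 3.63
    ys = np.where(np.arange(n_residues) % 2 == 0, 0.0, 1.1)
    zs = np.zeros(n_residues)
    coords = np.stack([xs, ys, zs], axis=1)
    aa = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=n_residues))
    return StructureModel(model_id or f"extended{n_residues}s{seed}",
                          np.arange(1, n_residues + 1), aa, coords, np.full(n_residues, 90.0))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def perturb_structure(m: StructureModel, sigma: float, seed: int = 0,
                      model_id: str | None = None) -> StructureModel:
    """Gaussian coordinate noise (std sigma per axis) plus a random proper
    rigid transform; confidence reset to 90."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = m.coords + rng.normal(scale=sigma, size=m.coords.shape) if sigma > 0 else m.coords.copy()
    R = _random_rotation(rng)
    t = rng.uniform(-50, 50, size=3)
    return StructureModel(model_id or f"{m.model_id}_pert", m.res_index.copy(), m.aa,
                          noisy @ R.T + t, np.full(len(m), 90.0))


def mutate_protein(seq: str, target_identity: float, seed: int = 0, indel_rate: float = 0.0) -> str:
    """Substitute a Bernoulli(1 - target_identity) fraction of positions with
    BLOSUM-plausible letters (positive-scoring replacements preferred); the
    initiator Met is kept.  Optional indels at ``indel_rate`` per position."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scheme = blosum62()
    out: list[str] = []
    for i, aa in enumerate(seq):
        if indel_rate > 0 and i > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(ALPHABET[rng.integers(0, 20)])  # insertion, then keep aa
        if i == 0 or rng.random() < target_identity or aa not in ALPHABET:
            out.append(aa)
            continue
        row = scheme.matrix[ALPHABET.index(aa), :20]
        plausible = [ALPHABET[j] for j in range(20) if row[j] > 0 and ALPHABET[j] != aa]
        if not plausible:
            plausible = [a for a in ALPHABET[:20] if a != aa]
        out.append(plausible[rng.integers(0, len(plausible))])
    return "".join(out)


def shuffle_protein(seq: str, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


# ---------------------------------------------------------------------------
# reference kit: the user-supplied inputs the mining pipeline expects

_CODON: dict[str, str] = {}
for codon, aa in sorted(CodonTable.unambiguous_dna_by_id[11].forward_table.items()):
    _CODON.setdefault(aa, codon)
_CODON["X"] = "NNN"


def back_translate(protein: str) -> str:
    """Deterministic codon choice per residue, ATG initiator, TAA stop."""
    codons = ["ATG" if i == 0 and aa == "M" else _CODON[aa] for i, aa in enumerate(protein)]
    return "".join(codons) + "TAA"


@dataclass
class ReferenceKit:
    """Paths and in-memory copies of the reference inputs for one fixture set."""

    root: Path
    eids_fasta: Path
    known_tps_fasta: Path
    refs_dir: Path
    catalytic_refs: Path
    eids_seqs: list[tuple[str, str]]
    known_tps_seqs: list[tuple[str, str]]
    ref_models: dict[str, StructureModel]
    family_parent: str  # shared candidate-family protein


_CATALYTIC_POSITIONS = [(30, "metal-binding"), (31, "metal-binding"), (70, "metal-binding"),
                        (71, "metal-binding"), (100, "basic"), (103, "basic"), (104, "metal-binding")]


def make_reference_kit(out_dir, seed: int = 0) -> ReferenceKit:
    """Write the E-IDS FASTA, known-TPS FASTA, reference fold PDBs, and a
    catalytic-residue JSON; all content is synthetic and seed-deterministic."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    eids = [(f"EIDS_ref{i + 1}", _random_protein(rng, 320)) for i in range(2)]
    known = [(f"knownTPS_{i + 1}", _random_protein(rng, 330)) for i in range(3)]
    eids_fa = root / "eids.fasta"
    known_fa = root / "known_tps.fasta"
    for path, entries in ((eids_fa, eids), (known_fa, known)):
        with open(path, "w") as fh:
            for sid, s in entries:
                fh.write(f">{sid}\n{s}\n")
    refs_dir = root / "refs"
    refs_dir.mkdir(exist_ok=True)
    ref_models = {
        "classI_ref": make_helical_bundle(6, 22, seed=seed + 11, model_id="classI_ref"),
        "classIB_ref": make_helical_bundle(5, 24, seed=seed + 12, model_id="classIB_ref"),
        "classIC_ref": make_helical_bundle(4, 26, seed=seed + 13, model_id="classIC_ref"),
    }
    for name, model in ref_models.items():
        write_pdb(model, refs_dir / f"{name}.pdb")
    cat = {
        name: [[pos, model.aa[pos - 1], role] for pos, role in _CATALYTIC_POSITIONS]
        for name, model in ref_models.items()
    }
    cat_path = root / "catalytic_refs.json"
    with open(cat_path, "w") as fh:
        json.dump(cat, fh, indent=1)
    family_parent = _random_protein(rng, 300)
    with open(root / "candidate_family.fasta", "w") as fh:
        fh.write(f">candidate_family_parent\n{family_parent}\n")
    return ReferenceKit(root, eids_fa, known_fa, refs_dir, cat_path, eids, known, ref_models, family_parent)


# ---------------------------------------------------------------------------
# synthetic genomes

@dataclass
class PlantedElement:
    role: str                       # anchor | candidate | known_tps_decoy | far_hypothetical | unrelated
    offset_from_anchor: int | None = None
    structure_noise_sigma: float = 1.0
    identity_to_parent: float = 0.75


def default_planted() -> list[PlantedElement]:
    return [
        PlantedElement("anchor", None, 0.0, 0.8),
        PlantedElement("candidate", 3, 1.0, 0.75),
        PlantedElement("known_tps_decoy", -2, 1.0, 0.7),
        PlantedElement("far_hypothetical", 13, 0.0, 1.0),
    ]


@dataclass
class FixtureSpec:
    """Layout of one synthetic genome; defaults emulate the study setting
    (one E-IDS anchor per genome, a +-10 gene window, one planted family
    member per genome)."""

    seed: int = 0
    n_contigs: int = 1
    genes_per_contig: int = 30
    window_k: int = 10
    planted: list[PlantedElement] = field(default_factory=default_planted)
    unrelated_hypothetical_every: int = 5  # every Nth unrelated gene is annotation-less

    def __post_init__(self) -> None:
        for p in self.planted:
            if p.role == "candidate" and p.offset_from_anchor is not None \
                    and abs(p.offset_from_anchor) > self.window_k:
                raise ValueError("candidate offset outside the +-window")
            if not 0 < p.identity_to_parent <= 1:
                raise ValueError("identity targets must be in (0, 1]")


def make_synthetic_genome(spec: FixtureSpec, out_dir, kit: ReferenceKit,
                          structures_dir=None) -> tuple[Path, Path, pd.DataFrame]:
    """Render a fixture genome: GenBank file, structure-model directory, truth table.

    Returns (genbank_path, structures_dir, truth_table).  The planted
    candidate's structure is a noised copy of the class I reference fold;
    the known-TPS decoy is sequence-similar to the known-TPS set but also
    fold-similar, so only the sequence-exclusion filter can remove it.
    Gene ids embed the genome id, so several genomes can share one
    ``structures_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    struct_dir = Path(structures_dir) if structures_dir is not None else out / "structures"
    struct_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genome_id = f"synthgenome{spec.seed}"

    anchor_rank = spec.genes_per_contig // 2
    by_rank: dict[int, PlantedElement] = {}
    for p in spec.planted:
        rank = anchor_rank if p.role == "anchor" else anchor_rank + (p.offset_from_anchor or 0)
        if not 0 <= rank < spec.genes_per_contig:
            raise ValueError(f"planted {p.role} falls off the contig (rank {rank})")
        if rank in by_rank:
            raise ValueError(f"two planted elements at rank {rank}")
        by_rank[rank] = p

    genes: list[GeneRecord] = []
    contig_seqs: dict[str, str] = {}
    truth_rows = []
    gene_no = 0
    unrelated_no = 0
    for c in range(spec.n_contigs):
        contig_id = f"{genome_id}_ctg{c + 1}"
        pos = 0
        parts: list[str] = []
        for rank in range(spec.genes_per_contig):
            gene_no += 1
            gene_id = f"{genome_id}_{gene_no:05d}"
            planted = by_rank.get(rank) if c == 0 else None
            structure: StructureModel | None = None
            sigma, identity = 0.0, 1.0
            role = "unrelated"
            if planted is None:
                unrelated_no += 1
                protein = _random_protein(rng, int(rng.integers(150, 300)))
                if spec.unrelated_hypothetical_every and unrelated_no % spec.unrelated_hypothetical_every == 0:
                    product = "hypothetical protein"
                    structure = make_extended_chain(150, seed=spec.seed * 1000 + gene_no, model_id=gene_id)
                else:
                    product = _PRODUCTS[int(rng.integers(0, len(_PRODUCTS)))]
            else:
                role = planted.role
                sigma, identity = planted.structure_noise_sigma, planted.identity_to_parent
                sub_seed = spec.seed * 1000 + gene_no
                if role == "anchor":
                    protein = mutate_protein(kit.eids_seqs[0][1], identity, seed=sub_seed)
                    product = "polyprenyl diphosphate synthase"
                elif role == "candidate":
                    protein = mutate_protein(kit.family_parent, identity, seed=sub_seed)
                    product = "hypothetical protein"
                    structure = perturb_structure(kit.ref_models["classI_ref"], sigma,
                                                  seed=sub_seed, model_id=gene_id)
                elif role == "known_tps_decoy":
                    protein = mutate_protein(kit.known_tps_seqs[0][1], identity, seed=sub_seed)
                    product = "hypothetical protein"
                    structure = perturb_structure(kit.ref_models["classI_ref"], sigma,
                                                  seed=sub_seed, model_id=gene_id)
                elif role == "far_hypothetical":
                    protein = _random_protein(rng, 250)
                    product = "hypothetical protein"
                    structure = make_extended_chain(150, seed=sub_seed, model_id=gene_id)
                else:
                    raise ValueError(f"unknown planted role {planted.role!r}")
            nt = back_translate(protein)
            strand = "-" if rank % 6 == 5 else "+"
            spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
            parts.append(spacer)
            start = pos + len(spacer)
            if strand == "-":
                from tpsmine.genome_io import _revcomp
                parts.append(_revcomp(nt))
            else:
                parts.append(nt)
            end = start + len(nt)
            pos = end
            genes.append(GeneRecord(gene_id, contig_id, start, end, strand, product, protein))
            if structure is not None:
                write_pdb(structure, struct_dir / f"{gene_id}.pdb")
            if planted is not None:
                truth_rows.append({
                    "gene_id": gene_id, "role": role,
                    "offset": planted.offset_from_anchor if planted.offset_from_anchor is not None else 0,
                    "sigma": sigma, "identity": identity,
                })
        contig_seqs[contig_id] = "".join(parts)

    annotation = GenomeAnnotation(genome_id, genes, contig_seqs)
    gbk_path = out / f"{genome_id}.gbk"
    write_genbank(annotation, gbk_path)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "role", "offset", "sigma", "identity"])
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return gbk_path, struct_dir, truth
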