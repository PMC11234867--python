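"""Orchestration of the four-filter mining workflow plus reporting.

Filter order follows the mining strategy figure: (a) anchor on E-IDS
genes, (b) hypothetical proteins within the +-k window, (c) structure
screen against reference terpene-synthase folds, (d) exclusion of
known-TPS-like sequences.  Candidates without an available structure
model are skipped with a log line and counted, mirroring a screen that
is restricted to proteins with models rather than failing on them.
All outputs are fully ordered, so re-running a config reproduces
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from tpsmine import align, candidate_typing, motifs as motifs_mod, neighborhood, phylogeny, structure
from tpsmine.genome_io import GenomeAnnotation, parse_genbank

log = logging.getLogger(__name__)

GENBANK_SUFFIXES = (".gb", ".gbk", ".gbff", ".genbank")
STRUCTURE_SUFFIXES = (".pdb", ".cif", ".mmcif")


class ConfigError(ValueError):
    """Bad or incomplete mining configuration."""


@dataclass
class MiningConfig:
    """All thresholds and input paths of one mining run.

    Defaults: +-10 gene window, anchor/known-TPS/homolog E-value 1e-5,
    pairwise typing E-value 0.1, TM-score 0.5, pLDDT trim 70, proximity
    cutoff 5.0 A.
    """

    genomes: list[str] = field(default_factory=list)
    structures: str = ""
    eids_fasta: str = ""
    known_tps_fasta: str = ""
    refs: str = ""
    catalytic_refs: str = ""
    window_k: float = 10
    anchor_e_max: float = 1e-5
    known_tps_e_max: float = 1e-5
    tm_min: float = 0.5
    plddt_min: float = 70.0
    type_e_max: float = 0.1
    homolog_e_max: float = 1e-5
    proximity_cutoff: float = 5.0
    motif_max_gap: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "MiningConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("anchor_e_max", "known_tps_e_max", "tm_min", "type_e_max",
                     "homolog_e_max", "proximity_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.window_k != math.inf and self.window_k < 1:
            raise ConfigError("window_k must be >= 1 (or infinite)")
        if not self.genomes:
            raise ConfigError("no genome files configured")
        for p in [*self.genomes, self.eids_fasta, self.known_tps_fasta, self.refs]:
            if not p or not Path(p).exists():
                raise ConfigError(f"required input path missing: {p!r}")
        if self.catalytic_refs and not Path(self.catalytic_refs).exists():
            raise ConfigError(f"catalytic_refs path missing: {self.catalytic_refs!r}")


@dataclass
class CandidateRecord:
    genome_id: str
    contig_id: str
    gene_id: str
    offset: int
    product: str
    length: int
    protein_seq: str
    anchor_gene_id: str
    anchor_evalue: float
    best_ref: str = ""
    tm_score: float = float("nan")
    rmsd: float = float("nan")
    known_tps_evalue: float = float("inf")
    type_label: str = ""
    motifs: list[str] = field(default_factory=list)
    proximal_residues: list[tuple[int, str, float]] = field(default_factory=list)


@dataclass
class CandidateReport:
    candidates: list[CandidateRecord]
    stage_counts: dict[str, int]
    partition: candidate_typing.TypePartition | None = None
    superpositions: dict[str, tuple[str, structure.Superposition]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.candidates)


def _read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _load_refs(refs_path) -> list[structure.StructureModel]:
    p = Path(refs_path)
    files = sorted(p.glob("*")) if p.is_dir() else [p]
    models = []
    for f in files:
        if f.suffix.lower() in STRUCTURE_SUFFIXES:
            m = structure.parse_structure(f)
            m.model_id = f.stem
            models.append(m)
    if not models:
        raise ConfigError(f"no reference structures under {refs_path}")
    return models


def _find_model_file(structures_dir: str, gene_id: str) -> Path | None:
    if not structures_dir:
        return None
    for suffix in STRUCTURE_SUFFIXES:
        p = Path(structures_dir) / f"{gene_id}{suffix}"
        if p.exists():
            return p
    return None


def _load_catalytic(path) -> dict[str, motifs_mod.CatalyticReference]:
    if not path:
        return {}
    with open(path) as fh:
        data = json.load(fh)
    return {
        ref_id: motifs_mod.CatalyticReference(ref_id, [(int(p), aa, role) for p, aa, role in rows])
        for ref_id, rows in data.items()
    }


def run_mining(config: MiningConfig) -> CandidateReport:
    """Execute the full four-filter workflow over the configured genomes."""
    config.validate()
    scheme = align.blosum62()
    eids_refs = _read_fasta(config.eids_fasta)
    known_tps = _read_fasta(config.known_tps_fasta)
    refs = _load_refs(config.refs)
    catrefs = _load_catalytic(config.catalytic_refs)
    ref_by_id = {m.model_id: m for m in refs}
    k = config.window_k if config.window_k != math.inf else 10 ** 9

    counts = {
        "genomes": 0, "anchors": 0, "window": 0, "hypothetical": 0, "deduplicated": 0,
        "with_model": 0, "structure_pass": 0, "after_known_tps": 0, "final": 0,
    }
    survivors: list[CandidateRecord] = []
    sups: dict[str, tuple[str, structure.Superposition]] = {}
    trimmed_models: dict[str, structure.StructureModel] = {}

    for genome_path in sorted(config.genomes):
        genome = parse_genbank(genome_path)
        counts["genomes"] += 1
        anchors = neighborhood.find_anchors(genome, eids_refs, scheme, config.anchor_e_max)
        counts["anchors"] += len(anchors)
        if not anchors:
            log.info("%s: no E-IDS anchors found", genome.genome_id)
            continue
        window: list[neighborhood.NeighborCandidate] = []
        for anchor in anchors:
            window.extend(neighborhood.extract_window(genome, anchor, k))
        counts["window"] += len(window)
        hypo = neighborhood.filter_hypothetical(window)
        counts["hypothetical"] += len(hypo)
        # dedupe overlapping anchor windows: keep the smallest |offset|
        best: dict[str, neighborhood.NeighborCandidate] = {}
        for c in sorted(hypo, key=lambda c: (abs(c.offset), c.anchor_gene_id)):
            best.setdefault(c.gene.gene_id, c)
        deduped = sorted(best.values(), key=lambda c: (c.gene.contig_id, c.gene.rank))
        counts["deduplicated"] += len(deduped)

        anchor_e = {a.gene.gene_id: a.best_hit.e_value for a in anchors}
        for cand in deduped:
            model_file = _find_model_file(config.structures, cand.gene.gene_id)
            if model_file is None:
                log.info("%s: no structure model for %s; skipped", genome.genome_id, cand.gene.gene_id)
                continue
            counts["with_model"] += 1
            model = structure.trim_low_confidence(structure.parse_structure(model_file), config.plddt_min)
            if len(model) < 20:
                log.info("%s: %s has <20 confident residues; fails structure screen",
                         genome.genome_id, cand.gene.gene_id)
                continue
            results = structure.screen_by_structure(model, refs, config.tm_min)
            top_ref, top_sup = results[0]
            log.info("%s: %s best fold %s TM=%.3f", genome.genome_id, cand.gene.gene_id,
                     top_ref, top_sup.tm_score)
            if top_sup.tm_score < config.tm_min:
                continue
            counts["structure_pass"] += 1
            sups[cand.gene.gene_id] = (top_ref, top_sup)
            trimmed_models[cand.gene.gene_id] = model
            survivors.append(CandidateRecord(
                genome_id=genome.genome_id,
                contig_id=cand.gene.contig_id,
                gene_id=cand.gene.gene_id,
                offset=cand.offset,
                product=cand.gene.product,
                length=cand.gene.length,
                protein_seq=cand.gene.protein_seq,
                anchor_gene_id=cand.anchor_gene_id,
                anchor_evalue=anchor_e[cand.anchor_gene_id],
                best_ref=top_ref,
                tm_score=top_sup.tm_score,
                rmsd=top_sup.rmsd,
            ))

    # filter (d): exclude sequences similar to known terpene synthases
    for rec in survivors:
        hit = align.best_hit(rec.protein_seq, known_tps, scheme, query_id=rec.gene_id)
        rec.known_tps_evalue = hit.e_value if hit else float("inf")
    final = [r for r in survivors if r.known_tps_evalue >= config.known_tps_e_max]
    for r in survivors:
        if r.known_tps_evalue < config.known_tps_e_max:
            log.info("%s excluded: known-TPS E=%.3g", r.gene_id, r.known_tps_evalue)
    counts["after_known_tps"] = len(final)
    final.sort(key=lambda r: (r.genome_id, r.contig_id, r.gene_id))
    counts["final"] = len(final)

    partition = None
    if final:
        table = candidate_typing.pairwise_evalues([(r.gene_id, r.protein_seq) for r in final], scheme)
        partition = candidate_typing.cluster_types(table, config.type_e_max)
        labels = partition.labels
        for r in final:
            r.type_label = labels[r.gene_id]

    for r in final:
        ref_id, sup = sups[r.gene_id]
        if ref_id not in catrefs:
            continue
        proximal = motifs_mod.map_proximal_residues(
            trimmed_models[r.gene_id], ref_by_id[ref_id], sup, catrefs[ref_id], config.proximity_cutoff)
        r.proximal_residues = proximal
        r.motifs = [m.pattern for m in
                    motifs_mod.extract_motifs([(p, aa) for p, aa, _ in proximal], config.motif_max_gap)]

    return CandidateReport(final, counts, partition, {r.gene_id: sups[r.gene_id] for r in final})


def write_report(report: CandidateReport, out_dir) -> None:
    """Write report.tsv/report.json/types.tsv/motifs.json plus per-candidate
    superposition JSON; deterministic ordering throughout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in report.candidates:
        row = asdict(r)
        row["motifs"] = ";".join(r.motifs)
        row["proximal_residues"] = ";".join(f"{p}{aa}@{d:.2f}" for p, aa, d in r.proximal_residues)
        rows.append(row)
    cols = ["genome_id", "contig_id", "gene_id", "offset", "product", "length",
            "anchor_gene_id", "anchor_evalue", "best_ref", "tm_score", "rmsd",
            "known_tps_evalue", "type_label", "motifs", "proximal_residues"]
    df = pd.DataFrame([{c: row[c] for c in cols} for row in rows], columns=cols)
    df.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6g")
    payload = {
        "stage_counts": report.stage_counts,
        "candidates": [
            {**{c: row[c] for c in cols}, "protein_seq": r.protein_seq}
            for row, r in zip(rows, report.candidates)
        ],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
    if report.partition is not None:
        candidate_typing.partition_to_tsv(report.partition, out / "types.tsv")
    motif_payload = {
        r.gene_id: {
            "motifs": r.motifs,
            "proximal_residues": [[p, aa, round(d, 3)] for p, aa, d in r.proximal_residues],
        }
        for r in report.candidates
    }
    with open(out / "motifs.json", "w") as fh:
        json.dump(motif_payload, fh, indent=1)
    sup_dir = out / "superpositions"
    sup_dir.mkdir(exist_ok=True)
    for gene_id, (ref_id, sup) in sorted(report.superpositions.items()):
        structure.superposition_to_json(sup, sup_dir / f"{gene_id}_vs_{ref_id}.json")


def run_homolog_census(
    report: CandidateReport,
    protein_db: list[tuple[str, str]],
    config: MiningConfig,
    out_dir=None,
) -> pd.DataFrame:
    """Per-type homolog counts, species counts, and a neighbor-joining tree.

    The type representative is its longest member; trees are built over
    representative + homologs and skipped (with a log line) below 3 taxa.
    """
    if not report.candidates:
        raise ValueError("empty report")
    scheme = align.blosum62()
    seq_by_id = {r.gene_id: r.protein_seq for r in report.candidates}
    rows = []
    trees: dict[str, str] = {}
    for k, cluster in enumerate(report.partition.clusters if report.partition else []):
        label = f"type-{k + 1}"
        rep_id = max(cluster, key=lambda cid: (len(seq_by_id[cid]), cid))
        rep_seq = seq_by_id[rep_id]
        if protein_db:
            hits, n_species = candidate_typing.find_homologs(
                rep_seq, protein_db, scheme, config.homolog_e_max, query_id=rep_id)
        else:
            hits, n_species = [], 0
        newick = ""
        taxa = [(rep_id, rep_seq)] + [(h.subject_id, dict(protein_db)[h.subject_id]) for h in hits
                                      if h.subject_id != rep_id]
        if len(taxa) >= 3:
            dm = phylogeny.distance_matrix(taxa, scheme)
            tree = phylogeny.neighbor_joining(dm)
            newick = phylogeny.write_newick(tree)
            trees[label] = newick
        else:
            log.info("%s: %d taxa, tree skipped", label, len(taxa))
        rows.append({"type_label": label, "representative": rep_id,
                     "n_homologs": len(hits), "n_species": n_species, "newick": newick})
    census = pd.DataFrame(rows, columns=["type_label", "representative", "n_homologs", "n_species", "newick"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        census.drop(columns="newick").to_csv(out / "census.tsv", sep="\t", index=False)
        for label, newick in trees.items():
            with open(out / f"tree_{label}.nwk", "w") as fh:
                fh.write(newick + "\n")
    return census
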