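"""Read annotated genomes into ordered gene tables.

Coordinates are 0-based half-open internally and converted at the I/O
boundary (GenBank and GFF3 are 1-based inclusive on disk).  Gene order
(``rank``) is by start coordinate within a contig, strand ignored:
neighborhood windows count genes, not base pairs.  Only protein-coding,
non-pseudo features enter the ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

_AA_CANON = set("ACDEFGHIKLMNPQRSTVWYX")
_NT_IUPAC = set("ACGTURYSWKMBDHVN")


class GenomeParseError(ValueError):
    """Raised when an annotation file cannot be interpreted."""


@dataclass
class GeneRecord:
    """One CDS feature with its protein translation and contig rank."""

    gene_id: str
    contig_id: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive
    strand: str         # '+' or '-'
    product: str
    protein_seq: str
    rank: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        bad = set(self.protein_seq) - _AA_CANON
        if bad:
            raise ValueError(f"gene {self.gene_id}: non-canonical residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.protein_seq)


@dataclass
class GenomeAnnotation:
    """All protein-coding genes of one genome, grouped and ranked per contig."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    contig_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._assign_ranks()

    def _assign_ranks(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in genome {self.genome_id}")
            seen.add(g.gene_id)
        by_contig: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        ordered: list[GeneRecord] = []
        for contig in by_contig:
            genes = sorted(by_contig[contig], key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(genes):
                g.rank = rank
            ordered.extend(genes)
        self.genes = ordered

    def contigs(self) -> list[str]:
        out: list[str] = []
        for g in self.genes:
            if g.contig_id not in out:
                out.append(g.contig_id)
        return out

    def contig_genes(self, contig_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def by_id(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def translate_cds(nt_seq: str, table_id: int = 11) -> str:
    """Translate a coding sequence to protein.

    Trailing partial codons are trimmed; the terminal stop is dropped and
    any internal stop (a broken CDS) becomes ``X``; ambiguous codons
    become ``X``; alternative initiator codons at position 0 yield ``M``
    under the chosen table (default 11, bacterial).
    """
    seq = nt_seq.upper().replace("U", "T")
    bad = set(seq) - _NT_IUPAC
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aa = str(Seq(seq).translate(table=table_id))
    if aa.endswith("*"):
        aa = aa[:-1]
    aa = aa.replace("*", "X")
    table = CodonTable.ambiguous_dna_by_id[table_id]
    if aa and seq[:3] in table.start_codons:
        aa = "M" + aa[1:]
    return aa


def _clean_protein(aa: str) -> str:
    return "".join(c if c in _AA_CANON else "X" for c in aa.upper().rstrip("*"))


def parse_genbank(path, genome_id: str | None = None, table_id: int = 11) -> GenomeAnnotation:
    """Parse a GenBank flat file into a :class:`GenomeAnnotation`.

    Translations come from the ``/translation`` qualifier when present,
    otherwise from :func:`translate_cds` on the spliced span.  Pseudogenes
    and CDS with coordinates that cannot be resolved on their own contig
    are skipped with a warning, not an error.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no records in GenBank file {path}")
    gid = genome_id or records[0].id
    genes: list[GeneRecord] = []
    contig_seqs: dict[str, str] = {}
    counter = 0
    for rec in records:
        contig_seqs[rec.id] = str(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                continue
            counter += 1
            try:
                start, end = int(feat.location.start), int(feat.location.end)
            except Exception:
                log.warning("%s: skipping CDS with unresolvable coordinates (%s)", rec.id, feat.location)
                continue
            if any(getattr(p, "ref", None) for p in feat.location.parts):
                log.warning("%s: skipping trans-spliced CDS %s", rec.id, feat.location)
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            gene_id = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"{rec.id}_cds{counter}"]))[0]
            product = feat.qualifiers.get("product", [""])[0]
            if "translation" in feat.qualifiers:
                protein = _clean_protein(feat.qualifiers["translation"][0])
            else:
                protein = translate_cds(str(feat.location.extract(rec.seq)), table_id)
            genes.append(GeneRecord(gene_id, rec.id, start, end, strand, product, protein))
    return GenomeAnnotation(gid, genes, contig_seqs)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def parse_gff_fasta(gff_path, fasta_path, genome_id: str | None = None, table_id: int = 11) -> GenomeAnnotation:
    """Parse GFF3 + genome FASTA; same contract as :func:`parse_genbank`.

    CDS lines sharing a ``Parent`` are spliced into one gene.  GFF3
    1-based inclusive coordinates are converted to 0-based half-open.
    """
    contig_seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contig_seqs:
        raise GenomeParseError(f"no sequences in FASTA {fasta_path}")
    gid = genome_id or next(iter(contig_seqs))
    # gene_id -> list of (seqid, start0, end0, strand, product)
    groups: dict[str, list[tuple[str, int, int, str, str]]] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeParseError(f"{gff_path}:{lineno}: expected 9 tab-separated columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in contig_seqs:
                raise GenomeParseError(f"{gff_path}:{lineno}: seqid {seqid!r} not in FASTA")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            key = attr.get("Parent", attr.get("ID", f"cds{lineno}"))
            product = attr.get("product", "")
            groups.setdefault(key, []).append((seqid, int(start) - 1, int(end), strand, product))
    genes: list[GeneRecord] = []
    for gene_id, parts in groups.items():
        parts.sort(key=lambda p: p[1])
        seqid = parts[0][0]
        strand = parts[0][3]
        product = next((p[4] for p in parts if p[4]), "")
        spans = [contig_seqs[seqid][p[1]:p[2]] for p in parts]
        if strand == "-":
            nt = "".join(_revcomp(s) for s in reversed(spans))
        else:
            nt = "".join(spans)
        protein = translate_cds(nt, table_id)
        genes.append(GeneRecord(gene_id, seqid, parts[0][1], parts[-1][2], strand, product, protein))
    return GenomeAnnotation(gid, genes, contig_seqs)


def write_gff_fasta(genome: GenomeAnnotation, gff_path, fasta_path) -> None:
    """Write a GenomeAnnotation as GFF3 + FASTA (round-trips with parse_gff_fasta)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(f"{g.contig_id}\t{genome.genome_id}\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n")
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contig_seqs.items()]
    SeqIO.write(records, str(fasta_path), "fasta")


def write_genbank(genome: GenomeAnnotation, path) -> None:
    """Write a GenomeAnnotation as a multi-record GenBank flat file."""
    records = []
    for cid, seq in genome.contig_seqs.items():
        rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description=f"{genome.genome_id} synthetic contig")
        rec.annotations["molecule_type"] = "DNA"
        for g in genome.contig_genes(cid):
            loc = SimpleLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
            quals = {
                "locus_tag": [g.gene_id],
                "product": [g.product] if g.product else [],
                "transl_table": ["11"],
                "translation": [g.protein_seq],
            }
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_protein_fasta(genome: GenomeAnnotation, path) -> None:
    """Export all proteins with ``genomeId|contigId|geneId|rank`` headers."""
    with open(path, "w") as fh:
        for g in genome.genes:
            if not g.protein_seq:
                continue
            fh.write(f">{genome.genome_id}|{g.contig_id}|{g.gene_id}|{g.rank}\n{g.protein_seq}\n")
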