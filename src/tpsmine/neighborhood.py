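"""Anchor-gene windowing: find E-IDS genes and their hypothetical neighbors.

The anchor is the E-isoprenyl diphosphate synthase (E-IDS) that makes the
prenyl diphosphate substrate of terpene synthases; candidates are the
annotation-less proteins within +-k genes of it on the same contig.
"""

from __future__ import annotations

from dataclasses import dataclass

from tpsmine.align import AlignmentHit, ScoringScheme, best_hit
from tpsmine.genome_io import GeneRecord, GenomeAnnotation

DEFAULT_HYPOTHETICAL_KEYWORDS = ("hypothetical", "uncharacterized", "unknown function", "DUF")


@dataclass
class AnchorHit:
    genome_id: str
    gene: GeneRecord
    best_hit: AlignmentHit


@dataclass
class NeighborCandidate:
    genome_id: str
    gene: GeneRecord
    anchor_gene_id: str
    offset: int  # rank difference from the anchor; never 0
    is_hypothetical: bool = False


def find_anchors(
    genome: GenomeAnnotation,
    eids_refs: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
) -> list[AnchorHit]:
    """Genes whose best alignment to any E-IDS reference has E-value < e_max."""
    if not eids_refs:
        raise ValueError("E-IDS reference set is empty")
    anchors = []
    for gene in genome.genes:
        if not gene.protein_seq:
            continue
        hit = best_hit(gene.protein_seq, eids_refs, scheme, query_id=gene.gene_id)
        if hit is not None and hit.e_value < e_max:
            anchors.append(AnchorHit(genome.genome_id, gene, hit))
    anchors.sort(key=lambda a: (a.gene.contig_id, a.gene.rank))
    return anchors


def extract_window(genome: GenomeAnnotation, anchor: AnchorHit, k: int = 10) -> list[NeighborCandidate]:
    """All genes within +-k ranks of the anchor on its contig (anchor excluded).

    ``k`` may be ``math.inf`` to disable the window (whole-contig mode).
    """
    if k < 1:
        raise ValueError("window half-width k must be >= 1")
    out = []
    for gene in genome.contig_genes(anchor.gene.contig_id):
        offset = gene.rank - anchor.gene.rank
        if offset == 0 or abs(offset) > k:
            continue
        out.append(NeighborCandidate(genome.genome_id, gene, anchor.gene.gene_id, offset))
    out.sort(key=lambda c: c.gene.rank)
    return out


def filter_hypothetical(
    cands: list[NeighborCandidate],
    keywords: tuple[str, ...] = DEFAULT_HYPOTHETICAL_KEYWORDS,
) -> list[NeighborCandidate]:
    """Keep candidates annotated as function-unknown.

    A product string matches case-insensitively against any keyword; an
    empty product also counts as hypothetical (unannotated CDS).
    """
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    lowered = [k.lower() for k in keywords]
    kept = []
    for c in cands:
        product = c.gene.product.strip().lower()
        if not product or any(k in product for k in lowered):
            c.is_hypothetical = True
            kept.append(c)
    return kept
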