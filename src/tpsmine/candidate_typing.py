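"""Cluster candidates into types by pairwise E-value; enumerate homologs.

Types are single-linkage clusters: connected components of the graph with
an edge wherever the pairwise E-value is below threshold (default 0.1).
Single linkage is the weakest assumption consistent with grouping by
"sequence similarity"; the directional E-value asymmetry (query vs
subject length) is resolved conservatively by taking the minimum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from tpsmine.align import AlignmentHit, ScoringScheme, search, smith_waterman


@dataclass
class TypePartition:
    """A disjoint cover of candidate ids; clusters labelled type-1, type-2, ..."""

    clusters: list[list[str]]
    threshold: float

    @property
    def labels(self) -> dict[str, str]:
        return {cid: f"type-{k + 1}" for k, cl in enumerate(self.clusters) for cid in cl}

    def __len__(self) -> int:
        return len(self.clusters)


def pairwise_evalues(cands: list[tuple[str, str]], scheme: ScoringScheme | None = None) -> pd.DataFrame:
    """Symmetric table of pairwise E-values; entry (i,j) is the smaller of the
    two directional values, diagonal 0."""
    if not cands:
        raise ValueError("need at least one candidate")
    ids = [c[0] for c in cands]
    n = len(cands)
    M = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            hij = smith_waterman(cands[i][1], cands[j][1], scheme)
            hji = smith_waterman(cands[j][1], cands[i][1], scheme)
            M[i, j] = M[j, i] = min(hij.e_value, hji.e_value)
    return pd.DataFrame(M, index=ids, columns=ids)


def cluster_types(evalue_table: pd.DataFrame, threshold: float = 0.1) -> TypePartition:
    """Connected components of the E < threshold similarity graph.

    Clusters are ordered by size descending, then by lexicographically
    smallest member; members sorted within each cluster.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ids = list(evalue_table.index)
    adj = csr_matrix((evalue_table.values < threshold).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for cid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(cid)
    clusters = sorted((sorted(g) for g in groups.values()), key=lambda g: (-len(g), g[0]))
    return TypePartition(clusters, threshold)


_ORGANISM_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


def species_of(header: str) -> str | None:
    """Organism token from a FASTA header, NCBI-style ``... [Genus species]``."""
    m = _ORGANISM_RE.search(header)
    return m.group(1) if m else None


def find_homologs(
    representative: str,
    protein_db: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
    query_id: str = "representative",
) -> tuple[list[AlignmentHit], int]:
    """Database hits below e_max plus a per-species deduplicated count.

    Subjects whose headers carry no organism token each count as their own
    species (conservative: no collapsing without evidence).
    """
    hits = search(representative, protein_db, scheme, e_max=e_max, query_id=query_id)
    species = {species_of(h.subject_id) or h.subject_id for h in hits}
    return hits, len(species)


def partition_to_tsv(partition: TypePartition, path) -> None:
    rows = [{"candidate_id": cid, "type_label": lab} for cid, lab in sorted(partition.labels.items())]
    pd.DataFrame(rows, columns=["candidate_id", "type_label"]).to_csv(path, sep="\t", index=False)
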