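"""Pairwise local protein alignment with Karlin-Altschul E-values.

Exact affine-gap Smith-Waterman (Gotoh) dynamic programming -- no seeding
heuristics, no composition-based statistics.  Candidate sets in the mining
pipeline are small, so correctness wins over speed; the DP inner loops are
JIT-compiled with numba.

A gap of length L costs ``gap_open + L * gap_extend`` (the open and the
first extension are charged together on the first gap residue, matching
BLAST's convention where an 11/1 scheme prices a length-1 gap at 12).

E-values follow E = K * m * n * exp(-lambda * S) with the standard gapped
BLOSUM62 constants by default; no effective-length (edge) correction is
applied, which users can offset by tightening thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

LN2 = math.log(2.0)


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs, and Karlin-Altschul constants.

    ``lam`` is in nats per raw-score unit.  The X row and column score 0
    against everything (neutral ambiguity), including X itself.
    """

    name: str
    matrix: np.ndarray  # (21, 21) int, indexed by ALPHABET
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (21, 21):
            raise ValueError("matrix must be 21x21 over ARNDCQEGHILKMFPSTWYVX")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0 or self.gap_extend > self.gap_open:
            raise ValueError("need 0 < gap_extend <= gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])


def blosum62(gap_open: int = 11, gap_extend: int = 1, lam: float = 0.267, K: float = 0.041) -> ScoringScheme:
    """BLOSUM62 with the standard gapped-search constants (lambda=0.267, K=0.041)."""
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(ALPHABET[:20]):
        for j, b in enumerate(ALPHABET[:20]):
            mat[i, j] = int(raw[a, b])
    # X is neutral by design, overriding BLOSUM62's mild X penalties
    mat[20, :] = 0
    mat[:, 20] = 0
    return ScoringScheme("BLOSUM62", mat, gap_open, gap_extend, lam, K)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical amino acid {exc.args[0]!r} in sequence") from None


@dataclass
class AlignmentHit:
    """A local alignment with raw/bit scores and an E-value."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_fraction: float
    q_range: tuple[int, int]  # half-open, 0-based
    s_range: tuple[int, int]
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_aligned(self) -> int:
        return len(self.aligned_pairs)


@njit(cache=False)
def _sw_fill(a, b, mat, go, ge):  # pragma: no cover - exercised via smith_waterman
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), -(10 ** 9), dtype=np.int64)  # gap in query (consumes b)
    F = np.full((m + 1, n + 1), -(10 ** 9), dtype=np.int64)  # gap in subject (consumes a)
    # traceback: 0 stop, 1 diag, 2 from E, 3 from F; for E/F: 1 open, 2 extend
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best, bi, bj = 0, 0, 0
    first = go + ge
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] - first
            ee = E[i, j - 1] - ge
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 2
            fo = H[i - 1, j] - first
            fe = F[i - 1, j] - ge
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 2
            diag = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if E[i, j] > h:
                h, p = E[i, j], 2
            if F[i, j] > h:
                h, p = F[i, j], 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    return best, bi, bj, ptrH, ptrE, ptrF


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    m: int | None = None,
    n: int | None = None,
) -> AlignmentHit:
    """Optimal local alignment of two protein sequences.

    Deterministic: the highest-scoring cell encountered first in row-major
    order ends the alignment, and traceback prefers matches over gaps, so
    among co-optimal alignments the one with the earliest endpoint and the
    fewest gap openings is returned.

    ``m``/``n`` override the search-space dimensions in the E-value (used
    by :func:`search` to price hits against a whole database).
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    scheme = scheme or blosum62()
    ea, eb = encode(a), encode(b)
    best, bi, bj, ptrH, ptrE, ptrF = _sw_fill(ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    pairs: list[tuple[int, int]] = []
    i, j, state = bi, bj, 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
        else:
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
    pairs.reverse()
    if pairs:
        q_range = (pairs[0][0], pairs[-1][0] + 1)
        s_range = (pairs[0][1], pairs[-1][1] + 1)
        ident = sum(1 for qi, sj in pairs if a[qi].upper() == b[sj].upper()) / len(pairs)
    else:
        q_range = s_range = (0, 0)
        ident = 0.0
    score = int(best)
    mm = m if m is not None else len(a)
    nn = n if n is not None else len(b)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bit_score(score, scheme),
        e_value=evalue(score, mm, nn, scheme),
        identity_fraction=ident,
        q_range=q_range,
        s_range=s_range,
        aligned_pairs=pairs,
    )


def bit_score(raw_score: int, scheme: ScoringScheme) -> float:
    """Normalized score in bits: (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.K)) / LN2


def evalue(raw_score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expected chance hits: E = K * m * n * exp(-lambda*S)."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return scheme.K * m * n * math.exp(-scheme.lam * raw_score)


def search(
    query: str,
    db: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Align a query against every database sequence; keep hits with E < e_max.

    The database size ``n`` in the E-value is the total residue count of
    ``db`` (one search space, as in BLAST).  Hits are sorted by ascending
    E-value, then subject id.
    """
    if not db:
        raise ValueError("database is empty")
    scheme = scheme or blosum62()
    n_total = sum(len(s) for _, s in db)
    hits = []
    for sid, sseq in db:
        if not sseq:
            continue
        hit = smith_waterman(query, sseq, scheme, query_id=query_id, subject_id=sid, m=len(query), n=n_total)
        if hit.raw_score > 0 and hit.e_value < e_max:
            hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, h.subject_id))
    return hits


def best_hit(query: str, db: list[tuple[str, str]], scheme: ScoringScheme | None = None,
             query_id: str = "query") -> AlignmentHit | None:
    """Best-scoring database hit regardless of threshold (None if nothing scores > 0)."""
    hits = search(query, db, scheme, e_max=math.inf, query_id=query_id)
    return hits[0] if hits else None


def exclude_known_tps(
    candidates: list[tuple[str, str]],
    known_tps_db: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
) -> list[tuple[str, str]]:
    """Drop candidates sequence-similar to any known terpene synthase.

    A candidate is excluded when its best hit against the known-TPS set has
    E-value below ``e_max``; order of survivors is preserved.
    """
    if not known_tps_db:
        raise ValueError("known-TPS database is empty")
    import logging

    log = logging.getLogger(__name__)
    kept = []
    for cid, seq in candidates:
        hit = best_hit(seq, known_tps_db, scheme, query_id=cid)
        if hit is not None and hit.e_value < e_max:
            log.info("excluded %s: similar to known TPS %s (E=%.3g)", cid, hit.subject_id, hit.e_value)
            continue
        kept.append((cid, seq))
    return kept


def hits_to_tsv(hits: list[AlignmentHit], path) -> None:
    """Write hits in tabular-BLAST style (1-based inclusive output coordinates)."""
    import pandas as pd

    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.subject_id,
            "pident": round(100.0 * h.identity_fraction, 2),
            "length": h.n_aligned,
            "qstart": h.q_range[0] + 1,
            "qend": h.q_range[1],
            "sstart": h.s_range[0] + 1,
            "send": h.s_range[1],
            "evalue": h.e_value,
            "bitscore": round(h.bit_score, 1),
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "length", "qstart", "qend",
                                "sstart", "send", "evalue", "bitscore"]).to_csv(path, sep="\t", index=False)
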