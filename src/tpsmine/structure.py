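"""Calpha structure models, Kabsch superposition, TM-score, fold screening.

Comparison is Calpha-only: predicted models carry per-residue confidence
(pLDDT, 0-100, stored in the B-factor column of AlphaFold-style files),
side chains are noisy and unnecessary for fold-level screening.

The sequence-independent aligner follows standard iterative-superposition
practice: gapless threading seeds, then cycles of {Kabsch fit -> distance-
based similarity matrix -> global dynamic programming with free end gaps}
until the aligned pair set repeats.  Similarity is scored by TM-score
normalized by the reference length; TM >= 0.5 is the conventional
same-fold criterion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"


@dataclass
class StructureModel:
    """Ordered residues of one chain: index, one-letter code, Calpha, confidence."""

    model_id: str
    res_index: np.ndarray          # (N,) int, strictly increasing
    aa: str                        # length N one-letter string
    coords: np.ndarray             # (N, 3) float, Angstrom
    confidence: np.ndarray | None = None  # (N,) in [0, 100], or None

    def __post_init__(self) -> None:
        self.res_index = np.asarray(self.res_index, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.res_index)
        if self.coords.shape != (n, 3) or len(self.aa) != n:
            raise ValueError(f"{self.model_id}: inconsistent residue arrays")
        if n > 1 and not np.all(np.diff(self.res_index) > 0):
            raise ValueError(f"{self.model_id}: res_index must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.model_id}: non-finite coordinates")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=np.float64)
            if self.confidence.shape != (n,):
                raise ValueError(f"{self.model_id}: confidence length mismatch")

    def __len__(self) -> int:
        return len(self.res_index)

    def subset(self, mask: np.ndarray, model_id: str | None = None) -> "StructureModel":
        return StructureModel(
            model_id or self.model_id,
            self.res_index[mask],
            "".join(c for c, keep in zip(self.aa, mask) if keep),
            self.coords[mask],
            None if self.confidence is None else self.confidence[mask],
        )


@dataclass
class Superposition:
    """A rigid transform mapping one model onto another over aligned pairs.

    ``rotation``/``translation`` map mobile coordinates x to R x + t in the
    reference frame; ``pairs`` are (mobile_position, reference_position)
    array indices; ``rmsd`` is the least-squares optimum over the pairs;
    ``tm_score`` is normalized by ``l_norm`` (the reference length).
    """

    rotation: np.ndarray
    translation: np.ndarray
    pairs: list[tuple[int, int]]
    rmsd: float
    tm_score: float
    l_norm: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def parse_structure(path, chain: str = "auto", predicted: bool = True) -> StructureModel:
    """Read a PDB or mmCIF file into a Calpha model.

    One residue per (chain, residue number), taking the Calpha atom; altloc
    ties resolved by highest occupancy then alphabetical altloc id.  The
    B-factor column becomes per-residue confidence when ``predicted`` is
    true (AlphaFold-style pLDDT).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if not names:
        raise ValueError(f"{path}: no chains")
    if chain == "auto":
        ch = model[0]
    else:
        if chain not in names:
            raise ValueError(f"{path}: chain {chain!r} not found; available: {names}")
        ch = model[chain]
    res_idx, aas, xyz, conf = [], [], [], []
    for res in ch:
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            continue
        cas.sort(key=lambda a: (-a.occ, a.altloc))
        ca = cas[0]
        res_idx.append(res.seqid.num)
        info = gemmi.find_tabulated_residue(res.name)
        one = info.one_letter_code.upper() if info else "X"
        aas.append(one if one.isalpha() and one in AA1_TO_3 else "X")
        xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
        conf.append(ca.b_iso)
    if not res_idx:
        raise ValueError(f"{path}: no Calpha atoms in chain {ch.name!r}")
    return StructureModel(
        st.name or str(path),
        np.array(res_idx),
        "".join(aas),
        np.array(xyz),
        np.array(conf) if predicted else None,
    )


def write_pdb(model: StructureModel, path, coords: np.ndarray | None = None) -> None:
    """Write a Calpha-only PDB; ``coords`` overrides the model's coordinates."""
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for k in range(len(model)):
            name3 = AA1_TO_3.get(model.aa[k], "UNK")
            b = 0.0 if model.confidence is None else float(model.confidence[k])
            x, y, z = xyz[k]
            fh.write(
                f"ATOM  {k + 1:>5}  CA  {name3} A{int(model.res_index[k]):>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C\n"
            )
        fh.write("END\n")


def trim_low_confidence(m: StructureModel, plddt_min: float = 70.0) -> StructureModel:
    """Drop residues below the pLDDT cutoff; original residue numbering kept."""
    if not 0 <= plddt_min <= 100:
        raise ValueError("plddt_min must be in [0, 100]")
    if m.confidence is None:
        log.warning("%s: no confidence values; returning model unchanged", m.model_id)
        return m
    return m.subset(m.confidence >= plddt_min)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid transform mapping points P onto points Q.

    Returns (R, t, rmsd) minimizing ||R P_i + t - Q_i|| in least squares;
    reflections are suppressed by sign-correcting the smallest singular
    direction, so det(R) = +1 always.
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (N, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def tm_d0(L: int) -> float:
    """Length-dependent TM-score distance scale; clamped to 0.5 A for short chains."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 21:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _tm_fit(
    pairs: list[tuple[int, int]],
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    l_norm: int,
    max_iter: int = 20,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximize the TM-score over superpositions fit on 'close' pair subsets.

    Standard iterative protocol: fit Kabsch on the current subset, evaluate
    the score over all pairs, keep the best transform, re-select the pairs
    within d0, repeat until the subset is stable.
    """
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    A, B = coordsA[ia], coordsB[ib]
    d0 = tm_d0(l_norm)
    subset = np.ones(len(pairs), dtype=bool)
    best = (-1.0, np.eye(3), np.zeros(3))
    seen: set[bytes] = set()
    for _ in range(max_iter):
        if subset.sum() < 3:
            break
        key = subset.tobytes()
        if key in seen:
            break
        seen.add(key)
        R, t, _ = kabsch(A[subset], B[subset])
        d = np.linalg.norm(A @ R.T + t - B, axis=1)
        score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)
        if score > best[0]:
            best = (score, R, t)
        subset = d < d0
    if best[0] < 0:  # tiny pair set: single unguarded fit
        R, t, _ = kabsch(A, B)
        d = np.linalg.norm(A @ R.T + t - B, axis=1)
        best = (float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm), R, t)
    return best


def tm_score(pairs: list[tuple[int, int]], coordsA: np.ndarray, coordsB: np.ndarray, l_norm: int) -> float:
    """TM-score of an aligned pair set, maximized over superpositions."""
    if not pairs:
        raise ValueError("pair list must be nonempty")
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    return _tm_fit(pairs, np.asarray(coordsA, float), np.asarray(coordsB, float), l_norm)[0]


@njit(cache=False)
def _nw_pairs(S, gap):  # pragma: no cover - exercised via structure_align
    """Global DP with free end gaps over a similarity matrix; returns pair arrays."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] + (0.0 if j == m else gap)
            left = H[i, j - 1] + (0.0 if i == n else gap)
            h, p = diag, 1
            if up > h:
                h, p = up, 2
            if left > h:
                h, p = left, 3
            H[i, j] = h
            ptr[i, j] = p
    out_i = np.empty(min(n, m), dtype=np.int64)
    out_j = np.empty(min(n, m), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 1:
            out_i[k] = i - 1
            out_j[k] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return out_i[:k][::-1].copy(), out_j[:k][::-1].copy()


def _quick_score(pairs: list[tuple[int, int]], A: np.ndarray, B: np.ndarray, l_norm: int) -> float:
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    R, t, _ = kabsch(A[ia], B[ib])
    d = np.linalg.norm(A[ia] @ R.T + t - B[ib], axis=1)
    d0 = tm_d0(l_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def structure_align(
    A: StructureModel,
    B: StructureModel,
    gap_penalty: float = -0.6,
    seed_stride: int = 5,
    max_iter: int = 30,
    min_len: int = 20,
) -> Superposition:
    """Sequence-independent alignment of model A onto reference B.

    Seeds are gapless threadings of A along B at every ``seed_stride``
    offset plus an N-terminal 30-mer seed; each seed is refined by
    iterating {Kabsch on current pairs -> similarity S_ij = 1/(1+(d_ij/d0)^2)
    -> global DP with gap penalty ``gap_penalty`` -> new pairs} until the
    pair set repeats or ``max_iter`` rounds.  The pair set with the highest
    TM-score normalized by len(B) wins.  Deterministic for fixed inputs.
    """
    nA, nB = len(A), len(B)
    if nA < min_len or nB < min_len:
        raise ValueError(f"both models need >= {min_len} residues (got {nA}, {nB})")
    l_norm = nB
    d0 = tm_d0(l_norm)
    ca, cb = A.coords, B.coords

    seeds: list[list[tuple[int, int]]] = []
    lo, hi = -(nA - min_len), nB - min_len
    for off in range(lo, hi + 1, seed_stride):
        pairs = [(i, i + off) for i in range(max(0, -off), min(nA, nB - off))]
        if len(pairs) >= min_len:
            seeds.append(pairs)
    nterm = min(30, nA, nB)
    seeds.append([(i, i) for i in range(nterm)])

    best_pairs: list[tuple[int, int]] | None = None
    best_score = -1.0
    for seed in seeds:
        pairs = seed
        seen: set[tuple] = set()
        for _ in range(max_iter):
            if len(pairs) < 3:
                break
            key = tuple(pairs)
            if key in seen:
                break
            seen.add(key)
            ia = np.array([p[0] for p in pairs])
            ib = np.array([p[1] for p in pairs])
            R, t, _ = kabsch(ca[ia], cb[ib])
            moved = ca @ R.T + t
            S = 1.0 / (1.0 + (cdist(moved, cb) / d0) ** 2)
            oi, oj = _nw_pairs(S, gap_penalty)
            pairs = list(zip(oi.tolist(), oj.tolist()))
            if len(pairs) >= 3:
                score = _quick_score(pairs, ca, cb, l_norm)
                if score > best_score:
                    best_score = score
                    best_pairs = pairs

    if best_pairs is None:
        raise RuntimeError("structure alignment failed to produce any pairs")
    tm, R, t = _tm_fit(best_pairs, ca, cb, l_norm)
    ia = np.array([p[0] for p in best_pairs])
    ib = np.array([p[1] for p in best_pairs])
    _, _, rmsd = kabsch(ca[ia], cb[ib])
    return Superposition(R, t, best_pairs, rmsd, tm, l_norm)


def screen_by_structure(
    candidate: StructureModel,
    refs: list[StructureModel],
    tm_min: float = 0.5,
) -> list[tuple[str, Superposition]]:
    """Align a candidate against every reference fold, sorted by TM-score.

    The candidate passes the screen when the best TM-score is >= tm_min
    (conventional same-fold threshold); the caller checks the top entry.
    """
    if not refs:
        raise ValueError("reference structure list is empty")
    results = [(ref.model_id, structure_align(candidate, ref)) for ref in refs]
    results.sort(key=lambda r: -r[1].tm_score)
    return results


def passes_screen(results: list[tuple[str, Superposition]], tm_min: float = 0.5) -> bool:
    return bool(results) and results[0][1].tm_score >= tm_min


def superposition_to_json(sup: Superposition, path=None) -> str:
    payload = {
        "rotation": sup.rotation.tolist(),
        "translation": sup.translation.tolist(),
        "pairs": [list(p) for p in sup.pairs],
        "rmsd": sup.rmsd,
        "tm_score": sup.tm_score,
        "l_norm": sup.l_norm,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
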