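"""Active-site-proximal residues, motif strings, and conservation logos.

After superposing a candidate onto a reference terpene synthase, the
candidate residues whose Calpha falls within a cutoff (default 5.0 A,
roughly side-chain contact range) of a reference catalytic residue are
collected and compressed into motif strings: runs of nearby positions
merge, with interior unlisted positions rendered as X (e.g. residues
R338/K341/D342 give "RXXKD").  Conservation across homologs is measured
per anchor column as Shannon information content in bits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tpsmine.align import ScoringScheme, smith_waterman
from tpsmine.structure import StructureModel, Superposition

LOG2_20 = math.log2(20.0)
_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CatalyticReference:
    """Catalytic residues of a reference model, by residue number."""

    ref_model_id: str
    residues: list[tuple[int, str, str]]  # (res_index, aa, role label)


@dataclass
class MotifString:
    """A short pattern over candidate residue numbers; X marks unlisted interior positions."""

    pattern: str
    positions: list[int]  # res_index of every listed (non-X) slot

    def __post_init__(self) -> None:
        span = self.positions[-1] - self.positions[0] + 1
        if len(self.pattern) != span:
            raise ValueError("pattern length must equal the residue-number span")


def map_proximal_residues(
    cand: StructureModel,
    ref: StructureModel,
    sup: Superposition,
    catref: CatalyticReference,
    cutoff: float = 5.0,
) -> list[tuple[int, str, float]]:
    """Candidate residues whose transformed Calpha lies within ``cutoff`` of a
    catalytic reference Calpha (closed bound, d <= cutoff); sorted by residue
    number, with the minimum distance reported."""
    ref_pos = {int(r): i for i, r in enumerate(ref.res_index)}
    cat_rows = []
    for res_index, _aa, _role in catref.residues:
        if res_index not in ref_pos:
            raise ValueError(f"catalytic residue {res_index} not in reference model {ref.model_id}")
        cat_rows.append(ref_pos[res_index])
    cat_xyz = ref.coords[cat_rows]
    moved = sup.transform(cand.coords)
    d = np.linalg.norm(moved[:, None, :] - cat_xyz[None, :, :], axis=2).min(axis=1)
    out = [
        (int(cand.res_index[i]), cand.aa[i], float(d[i]))
        for i in np.flatnonzero(d <= cutoff)
    ]
    out.sort(key=lambda r: r[0])
    return out


def extract_motifs(proximal: list[tuple[int, str]], max_gap: int = 3) -> list[MotifString]:
    """Merge proximal residues into motif strings, left to right.

    Successive residues whose numbers differ by at most ``max_gap + 1``
    join one motif; skipped interior positions become X.
    """
    items = sorted((int(p[0]), p[1]) for p in proximal)
    if not items:
        return []
    motifs: list[MotifString] = []
    run: list[tuple[int, str]] = [items[0]]
    for pos, aa in items[1:]:
        if pos - run[-1][0] <= max_gap + 1:
            run.append((pos, aa))
        else:
            motifs.append(_render(run))
            run = [(pos, aa)]
    motifs.append(_render(run))
    return motifs


def _render(run: list[tuple[int, str]]) -> MotifString:
    start = run[0][0]
    chars = ["X"] * (run[-1][0] - start + 1)
    for pos, aa in run:
        chars[pos - start] = aa
    return MotifString("".join(chars), [p for p, _ in run])


def star_msa(
    anchor_seq: str,
    homolog_seqs: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Star multiple alignment projected onto the anchor's columns.

    Each homolog is aligned pairwise to the anchor; columns that would be
    insertions relative to the anchor are dropped, so every row has exactly
    one symbol (residue or ``-``) per anchor position.  Row index is the
    homolog id, columns are 0-based anchor positions.
    """
    if not homolog_seqs:
        raise ValueError("need at least one homolog")
    rows = {}
    for hid, hseq in homolog_seqs:
        row = ["-"] * len(anchor_seq)
        hit = smith_waterman(hseq, anchor_seq, scheme, query_id=hid, subject_id="anchor")
        for hi, ai in hit.aligned_pairs:
            row[ai] = hseq[hi]
        rows[hid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(len(anchor_seq)))


def column_conservation(msa: pd.DataFrame, pseudocount: float = 0.0) -> tuple[pd.Series, pd.DataFrame]:
    """Per-column information content (bits) and letter heights.

    IC = log2(20) - H over the non-gap symbols of the column (X and gaps
    excluded from the entropy); heights are frequency x IC, the usual
    sequence-logo scaling.  All-gap columns get IC 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ics, heights = [], []
    for col in msa.columns:
        symbols = [s for s in msa[col] if s in _LETTERS]
        counts = np.array([symbols.count(a) for a in _LETTERS], dtype=float) + pseudocount
        total = counts.sum()
        if total == 0:
            ics.append(0.0)
            heights.append(np.zeros(20))
            continue
        freq = counts / total
        nz = freq[freq > 0]
        h = float(-(nz * np.log2(nz)).sum())
        ic = max(0.0, LOG2_20 - h)
        ics.append(ic)
        heights.append(freq * ic)
    ic_series = pd.Series(ics, index=msa.columns, name="information_content")
    height_df = pd.DataFrame(heights, index=msa.columns, columns=list(_LETTERS))
    return ic_series, height_df


def motif_with_alternation(
    motif: MotifString,
    msa: pd.DataFrame,
    anchor_positions: dict[int, int],
    joint_min: float = 0.8,
) -> str:
    """Motif pattern annotated with cross-homolog alternation groups.

    A listed slot becomes ``(A/B)`` when neither letter alone reaches the
    ``joint_min`` frequency in the homolog column but the top two jointly
    do (the conservation-report convention behind patterns like D(N/D));
    slots keep their single letter when it dominates and fall back to the
    anchor letter otherwise.  ``anchor_positions`` maps candidate residue
    numbers to 0-based MSA columns.
    """
    out = []
    listed = dict(zip(motif.positions, (c for c in motif.pattern if c != "X")))
    start = motif.positions[0]
    for k, ch in enumerate(motif.pattern):
        pos = start + k
        if ch == "X" or pos not in anchor_positions:
            out.append(ch)
            continue
        col = anchor_positions[pos]
        symbols = [s for s in msa[col] if s in _LETTERS]
        if not symbols:
            out.append(ch)
            continue
        freq = pd.Series(symbols).value_counts(normalize=True)
        top = freq.index[0]
        if freq.iloc[0] >= joint_min:
            out.append(top)
        elif len(freq) > 1 and freq.iloc[0] + freq.iloc[1] >= joint_min:
            out.append(f"({top}/{freq.index[1]})")
        else:
            out.append(listed.get(pos, ch))
    return "".join(out)


def motif_report(motifs: list[MotifString], proximal: list[tuple[int, str, float]], path=None) -> str:
    payload = {
        "motifs": [{"pattern": m.pattern, "positions": m.positions} for m in motifs],
        "proximal_residues": [
            {"res_index": p, "aa": aa, "min_distance": round(d, 3)} for p, aa, d in proximal
        ],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def logo_matrix_tsv(msa: pd.DataFrame, path, pseudocount: float = 0.0) -> None:
    """Export position x 20 letter heights for standard logo plotters."""
    ic, heights = column_conservation(msa, pseudocount)
    df = heights.copy()
    df.insert(0, "information_content", ic)
    df.index.name = "position"
    df.to_csv(path, sep="\t")
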