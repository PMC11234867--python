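"""Distance-based homolog phylogeny: identity distances, neighbor joining, Newick.

The distance between two proteins is 1 minus the identity fraction of
their optimal local alignment (optionally Kimura-corrected for multiple
hits).  Neighbor joining is the plain Saitou-Nei/Studier-Keppler scheme
with a deterministic tie-break and non-negative branch lengths; on an
additive matrix it recovers the generating tree exactly.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from tpsmine.align import ScoringScheme, smith_waterman


def distance_matrix(
    seqs: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    correction: str = "none",
) -> DistanceMatrix:
    """Pairwise 1 - identity distances, clamped to [0, 1].

    A pair with no positive-scoring local alignment gets distance 1.
    ``correction="kimura"`` applies d = -ln(1 - p - p^2/5) to the
    proportion of differences p (capped below saturation).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [s[0] for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hit = smith_waterman(seqs[i][1], seqs[j][1], scheme)
            if hit.raw_score <= 0 or not hit.aligned_pairs:
                p = 1.0
            else:
                p = min(1.0, max(0.0, 1.0 - hit.identity_fraction))
            if correction == "kimura":
                arg = 1.0 - p - p * p / 5.0
                p = -math.log(arg) if arg > 1e-6 else 10.0
            elif correction != "none":
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree, rooted (trifurcating) at the final join.

    Q-matrix pair selection with ties broken by the lexicographically
    smallest (name, name) pair; negative branch lengths are clamped to 0
    with the deficit moved to the sibling branch.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    names = list(ids)
    D = {a: {b: float(dm[a, b]) for b in names} for a in names}
    counter = 0
    while len(names) > 3:
        n = len(names)
        r = {a: sum(D[a][b] for b in names if b != a) for a in names}
        best = None
        for x in range(n):
            for y in range(x + 1, n):
                a, b = names[x], names[y]
                q = (n - 2) * D[a][b] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        la = D[a][b] / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = D[a][b] - la
        if la < 0:
            la, lb = 0.0, D[a][b]
        if lb < 0:
            lb, la = 0.0, D[a][b]
        u = f"__nj{counter}"
        counter += 1
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        nodes[u] = TreeNode(children=[na, nb])
        D[u] = {}
        for c in names:
            if c in (a, b):
                continue
            duc = (D[a][c] + D[b][c] - D[a][b]) / 2.0
            D[u][c] = duc
            D[c][u] = duc
        for c in (a, b):
            D.pop(c, None)
            for row in D.values():
                row.pop(c, None)
        names = [c for c in names if c not in (a, b)] + [u]
    a, b, c = sorted(names)
    la = (D[a][b] + D[a][c] - D[b][c]) / 2.0
    lb = (D[a][b] + D[b][c] - D[a][c]) / 2.0
    lc = (D[a][c] + D[b][c] - D[a][b]) / 2.0
    children = []
    for name, length in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(name)
        node.length = max(0.0, length)
        children.append(node)
    return TreeNode(children=children)


def _quote(name: str) -> str:
    if any(ch in name for ch in " '(),:;[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize with branch lengths to 6 decimal places; round-trip parseable."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            body = _quote(node.name or "")
        else:
            body = "(" + ",".join(render(ch) for ch in node.children) + ")"
            if node.name:
                body += _quote(node.name)
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    text = render(tree) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def edge_table(tree: TreeNode) -> dict[frozenset, float]:
    """Leaf-set bipartition -> branch length, for unrooted tree comparison.

    Pendant edges key on the single leaf; internal edges on the smaller
    side of the split.  Lengths of edges touching the (arbitrary) root are
    only comparable for trifurcating NJ roots.
    """
    leaves = frozenset(t.name for t in tree.tips())
    table: dict[frozenset, float] = {}
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        below = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        other = leaves - below
        key = below if (len(below), sorted(below)) <= (len(other), sorted(other)) else other
        table[key] = table.get(key, 0.0) + node.length
    return table


def distance_matrix_tsv(dm: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
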