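"""Independent oracles used by the tests: brute-force local alignment and
random additive trees.  These deliberately share no code with the package
paths they check."""

from itertools import combinations

import numpy as np


def brute_local_score(a: str, b: str, scheme) -> int:
    """Exhaustive optimal local alignment score for short sequences.

    Enumerates every monotone set of matched pairs; the gaps between
    consecutive pairs are charged affine (open + length * extend) once per
    sequence, which covers all alignments that could be optimal (splitting
    a gap run only adds open charges).  Exponential, fine for length <= 8.
    """
    m, n = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    best = 0
    for k in range(1, min(m, n) + 1):
        for qi in combinations(range(m), k):
            for sj in combinations(range(n), k):
                score = 0
                for t in range(k):
                    score += scheme.score(a[qi[t]], b[sj[t]])
                    if t:
                        dq = qi[t] - qi[t - 1] - 1
                        ds = sj[t] - sj[t - 1] - 1
                        if dq:
                            score -= go + dq * ge
                        if ds:
                            score -= go + ds * ge
                if score > best:
                    best = score
    return best


def union_find_components(n_nodes, edges):
    """Connected components by plain union-find (oracle for cluster_types)."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for i in range(n_nodes):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: sorted(s))


class _Node:
    def __init__(self, taxon=None, children=None, length=0.0):
        self.taxon = taxon
        self.children = children or []
        self.length = length

    def leaves(self):
        if self.taxon is not None:
            return [self.taxon]
        return [t for ch in self.children for t in ch.leaves()]


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with branch lengths in [0.1, 1].

    Returns (ids, distance matrix, edge table) where the edge table maps
    leaf-set bipartitions (keyed on the smaller side) to total branch
    length, matching tpsmine.phylogeny.edge_table conventions.
    """
    ids = [f"t{i}" for i in range(n_taxa)]

    def build(taxa):
        if len(taxa) == 1:
            return _Node(taxon=taxa[0])
        cut = int(rng.integers(1, len(taxa)))
        left, right = build(taxa[:cut]), build(taxa[cut:])
        left.length = float(rng.uniform(0.1, 1.0))
        right.length = float(rng.uniform(0.1, 1.0))
        return _Node(children=[left, right])

    order = list(ids)
    rng.shuffle(order)
    root = build(order)

    # pairwise distances by merging leaf->subtree-root distances upward
    n = len(ids)
    index = {t: i for i, t in enumerate(ids)}
    D = np.zeros((n, n))

    def depths(node):
        if node.taxon is not None:
            return {node.taxon: node.length}
        child_maps = [depths(ch) for ch in node.children]
        for x in range(len(child_maps)):
            for y in range(x + 1, len(child_maps)):
                for ta, da in child_maps[x].items():
                    for tb, db in child_maps[y].items():
                        D[index[ta], index[tb]] = D[index[tb], index[ta]] = da + db
        merged = {}
        for cm in child_maps:
            for t, d in cm.items():
                merged[t] = d + node.length
        return merged

    root.length = 0.0
    depths(root)

    all_leaves = frozenset(ids)
    table = {}

    def collect(node, is_root):
        if not is_root:
            below = frozenset(node.leaves())
            other = all_leaves - below
            key = below if (len(below), sorted(below)) <= (len(other), sorted(other)) else other
            table[key] = table.get(key, 0.0) + node.length
        for ch in node.children:
            collect(ch, False)

    collect(root, True)
    return ids, D, table
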