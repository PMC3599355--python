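"""Neighbor joining, bootstrap resampling, and majority-rule consensus.

The tree builder is the agglomerative neighbor-joining algorithm on a
distance matrix: at each step the pair minimizing
Q(i,j) = (k-2) d(i,j) - r_i - r_j is joined, with deterministic
tie-breaking on the lexicographically smallest leaf-name pair. Negative
branch-length estimates are clamped to zero with the deficit transferred to
the sister edge, so all output lengths are non-negative. On an exactly
additive matrix the unrooted topology and all path lengths are recovered.

Bootstrap support is estimated by resampling alignment columns with
replacement, rebuilding distances and the NJ tree per replicate, and
reporting per-split occurrence percentages on a majority-rule consensus
(extended, by default, with compatible minority splits in frequency order).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .align import Alignment, DistanceMatrix
from .tree import Node, Tree

_TIE_TOL = 1e-12


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build the unrooted NJ tree (trifurcating root) from a distance matrix."""
    k = len(dm)
    if k < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes = [Node(name=t) for t in dm.ids]
    reps = list(dm.ids)  # smallest leaf name per active node, for tie-breaks

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + _TIE_TOL)
        pairs = {tuple(sorted((int(a), int(b)))) for a, b in ties}
        i, j = min(pairs, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))

        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)

        child_i, child_j = nodes[i], nodes[j]
        child_i.length = vi
        child_j.length = vj
        parent = Node(children=[child_i, child_j])

        du = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = np.maximum(du[keep], 0.0)
        D = newD
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[x] for x in keep] + [parent]
        reps = [reps[x] for x in keep] + [new_rep]

    # final trifurcation via the three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        node.length = max(float(length), 0.0)
    return Tree(Node(children=nodes))


def bootstrap_trees(
    msa: Alignment,
    n: int = 1000,
    seed: int = 0,
    model: str = "p-distance",
) -> list[Tree]:
    """NJ trees from ``n`` column-resampled replicates of the alignment.

    Each replicate draws alignment columns with replacement to the original
    length, recomputes the distance matrix under ``model`` and rebuilds the
    NJ tree. Fully reproducible from ``seed``; replicate topologies are
    invariant under permutation of the input row order because column draws
    depend only on the seed and tie-breaking is by taxon name.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    enc = msa.encoded()
    ids = list(msa.ids)
    ntax, L = enc.shape
    trees = []
    for _ in range(n):
        cols = rng.integers(0, L, size=L)
        sub = enc[:, cols]
        d = np.zeros((ntax, ntax))
        for a in range(ntax):
            for b in range(a + 1, ntax):
                both = (sub[a] >= 0) & (sub[b] >= 0)
                scorable = int(both.sum())
                if scorable == 0:
                    raise ValueError(f"replicate has no shared columns for {ids[a]}/{ids[b]}")
                p = float(np.sum(sub[a][both] != sub[b][both])) / scorable
                if model == "poisson":
                    if p >= 1.0:
                        raise ValueError("saturated replicate pair under poisson model")
                    p = -np.log1p(-p)
                d[a, b] = d[b, a] = p
        trees.append(neighbor_joining(DistanceMatrix(ids, d)))
    return trees


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def majority_consensus(
    trees: list[Tree], threshold: float = 50.0, extended: bool = True
) -> Tree:
    """Majority-rule consensus with per-node support percentages.

    Splits occurring in more than ``threshold`` percent of the input trees
    are retained; in extended mode, remaining splits are added greedily in
    decreasing frequency when compatible with everything already accepted.
    Node support is the split's occurrence percentage in (0, 100].
    """
    if not trees:
        raise ValueError("no trees to summarize")
    leafsets = {frozenset(t.leaf_names()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees have mismatched leaf sets")
    leaves = leafsets.pop()
    ref = min(leaves)
    ntrees = len(trees)

    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(set(t.bipartitions().keys()))

    freqs = {c: 100.0 * k / ntrees for c, k in counts.items()}
    ordered = sorted(
        freqs.items(), key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0]))
    )
    selected: list[tuple[frozenset[str], float]] = []
    for clade, freq in ordered:
        if freq > threshold:
            selected.append((clade, freq))
        elif extended and all(_compatible(clade, c) for c, _ in selected):
            selected.append((clade, freq))

    # Build the tree rooted at the reference taxon's side. Clades are
    # mutually compatible and all exclude ref; processing by ascending size
    # attaches every clade/leaf to its immediate parent.
    selected.sort(key=lambda cf: (len(cf[0]), sorted(cf[0])))
    leaf_nodes = {name: Node(name=name) for name in leaves}
    clade_nodes: list[tuple[frozenset[str], Node]] = []
    assigned_leaves: set[str] = set()
    placed: set[int] = set()
    for clade, freq in selected:
        node = Node(support=freq)
        for idx, (sub, subnode) in enumerate(clade_nodes):
            if idx not in placed and sub <= clade:
                node.children.append(subnode)
                placed.add(idx)
        for name in sorted(clade):
            if name not in assigned_leaves:
                node.children.append(leaf_nodes[name])
                assigned_leaves.add(name)
        clade_nodes.append((clade, node))
    root = Node(children=[leaf_nodes[ref]])
    for name in sorted(leaves - assigned_leaves - {ref}):
        root.children.append(leaf_nodes[name])
    for idx, (_, node) in enumerate(clade_nodes):
        if idx not in placed:
            root.children.append(node)
    return Tree(root)
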