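"""Distance-matrix phylogeny over query sequences and deterministic binning.

The crop-library design groups candidate sequences by how their queries
fall in a phylogenetic tree, then samples every group.  Published
workflows do this by eye; here the whole chain is deterministic:
p-distances from a multiple alignment (any aligner; pairwise global
alignments are an accepted fallback), neighbor joining, and a tree cut
into ``k`` bins by removing the longest internal branches.

Containers are scikit-bio's: :class:`skbio.DistanceMatrix` (validates
symmetry, hollowness and finiteness) and :class:`skbio.TreeNode` (newick
round-trip and path-length queries for free).

Neighbor joining is implemented here rather than delegated because the
binning contract pins behaviours the library routine leaves open:
negative branch lengths are clamped to zero with the deficit moved to the
sister branch, and Q-matrix ties resolve to the smallest index pair, so
the same matrix always yields the same tree.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seqio import ProteinRecord

__all__ = [
    "pdistance_matrix",
    "distance_matrix_from_pairwise",
    "neighbor_joining",
    "cut_tree",
    "read_newick",
    "write_newick",
]


def pdistance_matrix(
    sequences: Sequence[ProteinRecord] | Sequence[tuple[str, str]],
    gap_chars: str = "-.",
) -> DistanceMatrix:
    """p-distance matrix from equal-length gapped (aligned) sequences.

    d[i][j] = mismatching columns / columns where neither sequence has a
    gap.  A pair with no gap-free column in common is an error.
    """
    pairs: list[tuple[str, str]] = []
    for item in sequences:
        if isinstance(item, ProteinRecord):
            pairs.append((item.id, item.residues))
        else:
            pairs.append((item[0], item[1].upper()))
    if len(pairs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(pairs[0][1])
    for label, seq in pairs:
        if len(seq) != length:
            raise ValueError(
                f"sequence {label!r} has length {len(seq)}, expected {length}"
            )
    labels = [label for label, _ in pairs]
    n = len(pairs)
    d = np.zeros((n, n))
    gaps = set(gap_chars)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pairs[i][1], pairs[j][1]
            comparable = mismatch = 0
            for x, y in zip(a, b):
                if x in gaps or y in gaps:
                    continue
                comparable += 1
                if x != y:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(d, ids=labels)


def distance_matrix_from_pairwise(
    records: Sequence[ProteinRecord],
) -> DistanceMatrix:
    """Fallback distance matrix from pairwise global alignments
    (1 - alignment identity).  Such distances are not guaranteed to be
    additive; the NJ tree is then a heuristic fit."""
    from .homolog_culling import global_align

    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - global_align(records[i], records[j]).identity
    return DistanceMatrix(d, ids=[r.id for r in records])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to the
    sister branch (sister itself floored at 0 in the doubly-negative
    degenerate case)."""
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Returns an unrooted tree represented as a :class:`TreeNode` whose
    root is the final three-way join (internal nodes have degree 3).
    Two labels yield a degenerate two-leaf tree with a warning.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        warnings.warn("two labels: returning degenerate two-leaf tree")
        half = dm[0, 1] / 2.0
        return TreeNode(
            children=[TreeNode(name=ids[0], length=half),
                      TreeNode(name=ids[1], length=half)]
        )

    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in ids]
    active = list(range(n))  # indices into rows of D, in creation order

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best: Optional[tuple[float, int, int]] = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best  # smallest (i, j) creation-order pair wins ties
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        # distances from the new node to the remaining active nodes
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # final three-way join: three-point closed form
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj = _clamp_pair(li, lj)
    lk = max(0.0, lk)
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


# ---------------------------------------------------------------------------
# Tree cutting
# ---------------------------------------------------------------------------

def _leaf_partition(tree: TreeNode, cut_ids: set[int]) -> list[list[str]]:
    """Leaf components of the tree after removing the edges above the
    nodes whose ``id()`` is in ``cut_ids``."""
    components: list[list[str]] = []

    def collect(node: TreeNode) -> list[str]:
        if node.is_tip():
            mine = [node.name]
        else:
            mine = []
            for child in node.children:
                below = collect(child)
                if id(child) in cut_ids:
                    if below:
                        components.append(below)
                else:
                    mine.extend(below)
        return mine

    top = collect(tree)
    if top:
        components.append(top)
    return components


def cut_tree(tree: TreeNode, k: int = 10) -> dict[str, int]:
    """Partition the tree's leaves into ``k`` bins by branch removal.

    Candidate cut edges form a fixed priority list: internal branches by
    decreasing length first, then leaf branches by decreasing length
    (internal branches alone cannot produce singleton bins at large
    ``k``); ties resolve by the lexicographically smallest leaf-label set
    under the edge.  Walking that list, an edge is cut only if it
    actually splits the current leaf partition, until ``k`` bins exist.
    Because the accepted cut sequence does not depend on ``k``, a larger
    ``k`` always refines a smaller one.  Bins are numbered 1..k by their
    smallest leaf label.
    """
    leaves = sorted(tip.name for tip in tree.tips())
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k={k} out of range 1..{len(leaves)}")

    internal_edges = []
    leaf_edges = []
    for node in tree.traverse(include_self=False):
        length = node.length if node.length is not None else 0.0
        clade = tuple(sorted(tip.name for tip in node.tips()))
        entry = (-length, clade, node)
        if node.is_tip():
            leaf_edges.append(entry)
        else:
            internal_edges.append(entry)
    internal_edges.sort(key=lambda e: (e[0], e[1]))
    leaf_edges.sort(key=lambda e: (e[0], e[1]))
    priority = [e[2] for e in internal_edges + leaf_edges]

    cut_ids: set[int] = set()
    partition = _leaf_partition(tree, cut_ids)
    for node in priority:
        if len(partition) >= k:
            break
        trial = cut_ids | {id(node)}
        trial_partition = _leaf_partition(tree, trial)
        if len(trial_partition) > len(partition):
            cut_ids = trial
            partition = trial_partition

    ordered = sorted(partition, key=min)
    assignment: dict[str, int] = {}
    for index, members in enumerate(ordered, start=1):
        for name in members:
            assignment[name] = index
    return assignment


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
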