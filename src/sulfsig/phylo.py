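"""Distances, neighbor-joining trees, bootstrap support, clade membership.

Distances are p-distances (mismatch fraction over pairwise shared non-gap
columns; no multiple-hit correction, matching a tree whose scale bar reads
in substitutions per site).  Neighbor joining follows Saitou & Nei's
Q-criterion agglomeration, with ties broken on the lexicographically
smallest label pair and negative branch lengths clamped to zero, so trees
are reproducible across platforms.  Bootstrap support of an internal edge
is the percentage of column-resampled replicate trees containing the same
unrooted leaf bipartition.  Clade membership roots the tree on the outgroup
attachment edge and asks whether a candidate descends from the most recent
common ancestor of the designated family leaves.
"""

from __future__ import annotations

import warnings
from io import StringIO
from typing import Dict, FrozenSet, Iterable, List, Set

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .conservation import GAP, Msa


class PhyloError(ValueError):
    pass


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix over alignment rows."""
    if msa.n_rows < 3:
        raise PhyloError("need at least 3 rows for a distance matrix")
    enc = np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in msa.rows])
    gap = ord(GAP)
    n = msa.n_rows
    d = np.zeros((n, n))
    nongap = enc != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = int(both.sum())
            if shared == 0:
                raise PhyloError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no non-gap columns"
                )
            mism = int((enc[i][both] != enc[j][both]).sum())
            d[i, j] = d[j, i] = mism / shared
    return DistanceMatrix(d, msa.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Q-ties break on the lexicographically smallest (sorted) label pair;
    negative branch lengths are clamped to zero without redistribution.
    Returns a trifurcating-root TreeNode representing the unrooted tree.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise PhyloError("need at least 3 taxa")
    d = np.asarray(dm.data, dtype=float)
    if np.any(d < 0):
        raise PhyloError("negative distances")
    nodes: List[TreeNode] = [TreeNode(name=l) for l in labels]
    names: List[str] = list(labels)  # tie-break key per active node

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((names[i], names[j]))), i, j)
            for i, j in cand if i < j
        )
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.extend([a, b])
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # final three-point formulas
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    root = TreeNode()
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = ln
        root.append(node)
    return root


def path_length_matrix(tree: TreeNode, labels: Iterable[str]) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    labels = list(labels)
    return DistanceMatrix(tree.cophenet().filter(labels).data, labels)


def _bipartitions(tree: TreeNode, all_tips: FrozenSet[str]) -> Set[FrozenSet[str]]:
    """Canonical unrooted bipartitions (smaller/lexicographic side) of internal edges."""
    out: Set[FrozenSet[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue  # trivial split
        comp = all_tips - side
        canon = min(side, comp, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def bootstrap_support(
    msa: Msa, n_replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree with internal-edge bootstrap supports (percent of replicates).

    Columns are resampled with replacement per replicate; each replicate
    tree's unrooted bipartitions are counted against the full-data tree.
    Supports are stored on internal nodes both as ``node.support`` and as
    the node name (Newick internal-label convention).  Deterministic given
    the seed.
    """
    if n_replicates < 1:
        raise PhyloError("n_replicates must be >= 1")
    tree = neighbor_joining(p_distance_matrix(msa))
    all_tips = frozenset(msa.ids)
    counts: Dict[FrozenSet[str], int] = {}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    rows = np.array([list(r) for r in msa.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row) for row in rows[:, cols]]
        try:
            rep_msa = Msa(list(zip(msa.ids, rep_rows)))
            rep_tree = neighbor_joining(p_distance_matrix(rep_msa))
        except (PhyloError, ValueError):
            continue  # degenerate resample (all-gap column / no shared columns)
        for bp in _bipartitions(rep_tree, all_tips):
            counts[bp] = counts.get(bp, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        canon = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * counts.get(canon, 0) / n_replicates
        node.support = support
        node.name = f"{support:g}"
    return tree


def to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    try:
        return TreeNode.read(StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise PhyloError(f"invalid Newick: {exc}") from exc


def clade_membership(
    tree: TreeNode,
    family_labels: Iterable[str],
    outgroup_labels: Iterable[str],
    candidate: str,
) -> str:
    """Classify ``candidate`` as "inside" or "outside" the family clade.

    The tree is rooted on the outgroup attachment edge; the candidate is
    inside iff it descends from the most recent common ancestor of the
    family leaves.  A non-monophyletic outgroup triggers a warning and the
    tree is rooted at the outgroup's MRCA instead.
    """
    family = set(family_labels)
    outgroup = set(outgroup_labels)
    if family & outgroup:
        raise PhyloError("family and outgroup labels overlap")
    tips = {t.name for t in tree.tips()}
    for lbl in family | outgroup | {candidate}:
        if lbl not in tips:
            raise PhyloError(f"label {lbl!r} is not a leaf of the tree")
    work = tree.copy()
    try:
        rooted = work.root_by_outgroup(sorted(outgroup))
    except Exception:
        warnings.warn("outgroup is not monophyletic; rooting at the outgroup MRCA")
        mrca = work.lca(sorted(outgroup))
        rooted = work.root_at(mrca) if mrca is not work else work
    mrca = rooted.lca(sorted(family))
    inside = any(t.name == candidate for t in mrca.tips(include_self=True))
    return "inside" if inside else "outside"
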