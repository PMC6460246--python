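"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's dynamic-programming and
agglomeration code paths: alignment scores come from exhaustive enumeration
of alignment paths, motif scores from enumeration of windows and masks, and
additive distance matrices from explicit path sums over randomly generated
trees.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# alignment enumeration


def enumerate_global_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best global affine-gap score over all alignment paths (terminal gaps scored).

    A gap run of length k costs gap_open + k * gap_extend.
    """
    best = [-np.inf]

    def step(i: int, j: int, score: float, state: int) -> None:
        # state: 0 diagonal/start, 1 gap-in-b (consuming a), 2 gap-in-a
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            step(i + 1, j + 1, score + matrix[a[i], b[j]], 0)
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            step(i + 1, j, score - cost, 1)
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            step(i, j + 1, score - cost, 2)

    step(0, 0, 0.0, 0)
    return best[0]


def enumerate_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best local score: max over all substring pairs (and the empty alignment)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = enumerate_global_score(a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend)
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# motif scan enumeration


def enumerate_best_motif_score(candidate: str, motif) -> float:
    """Best normalized motif score by explicit window/mask enumeration."""
    from itertools import combinations

    opts = [k for k, p in enumerate(motif.positions) if p.kind == "optional"]
    wsum = sum(p.weight for p in motif.positions if p.kind == "fixed")
    best = None
    for r in range(len(opts) + 1):
        for included in combinations(opts, r):
            keep = [p for k, p in enumerate(motif.positions)
                    if p.kind != "optional" or k in included]
            span = len(keep)
            if span > len(candidate):
                continue
            for start in range(len(candidate) - span + 1):
                score = sum(
                    p.weight
                    for off, p in enumerate(keep)
                    if p.kind == "fixed" and candidate[start + off] in p.allowed
                )
                norm = score / wsum
                best = norm if best is None else max(best, norm)
    return 0.0 if best is None else best


# ---------------------------------------------------------------------------
# additive distance matrices from random trees


def random_additive_matrix(
    rng: np.random.Generator, n_taxa: int
) -> Tuple[List[str], np.ndarray]:
    """Random binary tree with positive branch lengths -> path-length matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths, built by random sequential attachment
    next_internal = [n_taxa]
    edges: Dict[int, Dict[int, float]] = {i: {} for i in range(n_taxa)}

    def connect(u: int, v: int, w: float) -> None:
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    def blen() -> float:
        return float(rng.uniform(0.1, 2.0))

    connect(0, 1, blen() + blen())
    for leaf in range(2, n_taxa):
        # pick a random existing edge and subdivide it with a new internal node
        all_edges = [(u, v) for u in edges for v in edges[u] if u < v]
        u, v = all_edges[rng.integers(0, len(all_edges))]
        w = edges[u].pop(v)
        edges[v].pop(u)
        mid = next_internal[0]
        next_internal[0] += 1
        cut = float(rng.uniform(0.2, 0.8)) * w
        connect(u, mid, cut)
        connect(mid, v, w - cut)
        connect(mid, leaf, blen())

    # all-pairs path lengths among leaves (Dijkstra is overkill: BFS on a tree)
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    d = (d + d.T) / 2.0  # remove float asymmetry from summation order
    return labels, d
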