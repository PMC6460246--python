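"""Pairwise and progressive protein alignment, homolog screening.

Pairwise global (Needleman-Wunsch) and local (Smith-Waterman) alignment use
BLOSUM62 with BLAST-style affine gaps by default (a gap of length k costs
open + k * extend, open 11, extend 1), so that locally recomputed percent
identity and query cover are comparable to BLASTp's reported figures.
Identity is counted over all alignment columns, gaps included in the
denominator (the BLAST convention; configurable).

Homolog screening emulates the family-expansion step used to collect
candidate 2-O-sulfatases: for each query, the top-N highest-identity
database subjects with identity strictly above the threshold (the published
procedure used >40% identity, 100 sequences per query).

The progressive multiple aligner builds a neighbor-joining guide tree from
pairwise p-distances and merges profiles leaf-to-root by profile-profile
global alignment with sum-of-pairs scoring.  It is intentionally simple (no
iterative refinement); externally computed alignments are accepted
everywhere an Msa is.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence as TSeq, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .conservation import GAP, Msa
from .seqcore import Sequence, SequenceSet


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus BLAST-style affine gap costs.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise AlignError("require gap_open >= gap_extend > 0")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    qstart: int  # 1-based ungapped coordinates in sequence a (the query)
    qend: int
    sstart: int
    send: int
    identity_percent: float
    query_cover_percent: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identities(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != GAP)


@dataclass(frozen=True)
class HomologHit:
    query: str
    subject: str
    identity_percent: float
    query_cover_percent: float
    alignment_length: int


def _make_aligner(s: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = s.matrix
    # Biopython scores the first gap position with open_gap_score and each
    # further position with extend_gap_score; BLAST's open cost is on top of
    # the per-position extension.
    al.open_gap_score = -(s.gap_open + s.gap_extend)
    al.extend_gap_score = -s.gap_extend
    return al


def _finish(a: Sequence, b: Sequence, aln, query_len: int) -> PairwiseAlignment:
    rows = (str(aln[0]), str(aln[1]))
    coords = aln.coordinates
    qstart, qend = int(coords[0, 0]) + 1, int(coords[0, -1])
    sstart, send = int(coords[1, 0]) + 1, int(coords[1, -1])
    cols = len(rows[0])
    idents = sum(1 for x, y in zip(*rows) if x == y and x != GAP)
    return PairwiseAlignment(
        aligned_a=rows[0],
        aligned_b=rows[1],
        score=float(aln.score),
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        identity_percent=100.0 * idents / cols,
        query_cover_percent=100.0 * (qend - qstart + 1) / query_len,
    )


def global_align(a: Sequence, b: Sequence, s: ScoringScheme = ScoringScheme()) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment under affine gaps (end gaps scored)."""
    if not a.residues or not b.residues:
        raise AlignError("cannot align an empty sequence")
    aligner = _make_aligner(s, "global")
    aln = aligner.align(a.residues, b.residues)[0]
    return _finish(a, b, aln, len(a))


def local_align(
    a: Sequence, b: Sequence, s: ScoringScheme = ScoringScheme()
) -> Optional[PairwiseAlignment]:
    """Optimal Smith-Waterman alignment; ``None`` when the best score is <= 0.

    ``a`` is the query: query cover is the aligned fraction of ``a``.
    """
    if not a.residues or not b.residues:
        raise AlignError("cannot align an empty sequence")
    aligner = _make_aligner(s, "local")
    res = aligner.align(a.residues, b.residues)
    if res.score <= 0 or len(res) == 0:
        return None
    return _finish(a, b, res[0], len(a))


def screen_homologs(
    queries: SequenceSet,
    db: SequenceSet,
    s: ScoringScheme = ScoringScheme(),
    min_identity: float = 40.0,
    top_n: int = 100,
    min_cover: Optional[float] = None,
) -> List[HomologHit]:
    """Per-query top-N local-alignment hits with identity strictly above threshold.

    Self-hits (same id) are excluded; hits sort by identity descending then
    subject id ascending.  ``min_cover`` optionally adds a query-cover floor
    (off by default; the published screen states only the identity cutoff).
    """
    out: List[HomologHit] = []
    for q in queries:
        hits: List[HomologHit] = []
        for subj in db:
            if subj.id == q.id:
                continue
            aln = local_align(q, subj, s)
            if aln is None:
                continue
            if aln.identity_percent <= min_identity:
                continue
            if min_cover is not None and aln.query_cover_percent < min_cover:
                continue
            hits.append(
                HomologHit(
                    query=q.id,
                    subject=subj.id,
                    identity_percent=aln.identity_percent,
                    query_cover_percent=aln.query_cover_percent,
                    alignment_length=aln.n_columns,
                )
            )
        hits.sort(key=lambda h: (-h.identity_percent, h.subject))
        out.extend(hits[:top_n])
    return out


def write_hit_table(hits: TSeq[HomologHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tidentity\tcover\tlength\n")
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity_percent:.1f}"
                f"\t{h.query_cover_percent:.1f}\t{h.alignment_length}\n"
            )


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _pairwise_p_distance(a: Sequence, b: Sequence, s: ScoringScheme) -> float:
    aln = global_align(a, b, s)
    shared = mism = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            shared += 1
            if x != y:
                mism += 1
    if shared == 0:
        raise AlignError(f"sequences {a.id!r} and {b.id!r} share no aligned residues")
    return mism / shared


_AA_INDEX = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWYX")}


def _profile_counts(rows: List[str]) -> np.ndarray:
    """(n_columns, 21) residue count matrix of a gapped profile."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(_AA_INDEX)))
    for r in rows:
        for j, c in enumerate(r):
            if c != GAP:
                counts[j, _AA_INDEX[c]] += 1
    return counts


def _profile_align(rows_a: List[str], rows_b: List[str], s: ScoringScheme) -> Tuple[List[str], List[str]]:
    """Global profile-profile alignment (Gotoh) with sum-of-pairs scoring.

    Column-column score is the count-weighted sum of substitution scores;
    gap costs scale with the number of rows in the opposing profile.
    """
    matrix = s.matrix
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    sub = np.array([[matrix[x, y] for y in letters] for x in letters])
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    la, lb = ca.shape[0], cb.shape[0]
    na, nb = len(rows_a), len(rows_b)
    # pair score S[i,j] = ca[i] @ sub @ cb[j]
    S = ca @ sub @ cb.T
    NEG = -1e30
    # three-state Gotoh over (la+1, lb+1); sum-of-pairs gap costs scale with
    # the number of sequence pairs crossing the gap (na * nb), matching the
    # count-summed substitution scores
    open_cost = (s.gap_open + s.gap_extend) * na * nb
    ext_cost = s.gap_extend * na * nb
    oa, ea = open_cost, ext_cost  # gap in B: consume an A column against gaps
    ob, eb = open_cost, ext_cost  # gap in A: consume a B column against gaps
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B, moving down (A column vs gaps)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A, moving right
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -oa - ea * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -ob - eb * (j - 1)
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        Mi1 = M[i - 1]
        Xi1 = X[i - 1]
        Yi1 = Y[i - 1]
        # X (down moves) can be computed rowwise
        x_open = Mi1 - oa
        x_ext = Xi1 - ea
        x_oy = Yi1 - oa
        X[i] = np.maximum(np.maximum(x_open, x_ext), x_oy)
        ptrX[i] = np.where(x_ext >= np.maximum(x_open, x_oy), 1, np.where(x_open >= x_oy, 0, 2))
        diag = np.maximum(np.maximum(Mi1[:-1], X[i - 1, :-1]), Y[i - 1, :-1])
        src = np.where(
            Mi1[:-1] >= np.maximum(X[i - 1, :-1], Y[i - 1, :-1]), 0,
            np.where(X[i - 1, :-1] >= Y[i - 1, :-1], 1, 2),
        )
        M[i, 1:] = diag + S[i - 1]
        ptrM[i, 1:] = src
        # Y (right moves) needs a sequential pass
        Mi = M[i]
        Yi = Y[i]
        for j in range(1, lb + 1):
            y_open = Mi[j - 1] - ob
            y_ext = Yi[j - 1] - eb
            y_ox = X[i, j - 1] - ob
            if y_ext >= y_open and y_ext >= y_ox:
                Yi[j] = y_ext
                ptrY[i, j] = 1
            elif y_open >= y_ox:
                Yi[j] = y_open
                ptrY[i, j] = 0
            else:
                Yi[j] = y_ox
                ptrY[i, j] = 2
    # traceback
    i, j = la, lb
    finals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(finals))
    out_a: List[str] = []
    out_b: List[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = ptrM[i, j]
            out_a.append("col")
            out_b.append("col")
            i -= 1
            j -= 1
            state = prev
        elif state == 1 and i > 0:
            prev = ptrX[i, j]
            out_a.append("col")
            out_b.append("gap")
            i -= 1
            state = prev
        elif state == 2 and j > 0:
            prev = ptrY[i, j]
            out_a.append("gap")
            out_b.append("col")
            j -= 1
            state = prev
        elif i > 0:
            out_a.append("col")
            out_b.append("gap")
            i -= 1
            state = 1
        else:
            out_a.append("gap")
            out_b.append("col")
            j -= 1
            state = 2
    out_a.reverse()
    out_b.reverse()
    # build merged rows
    new_a: List[str] = ["" for _ in rows_a]
    new_b: List[str] = ["" for _ in rows_b]
    ia = ib = 0
    for ma, mb in zip(out_a, out_b):
        if ma == "col":
            for k, r in enumerate(rows_a):
                new_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                new_a[k] += GAP
        if mb == "col":
            for k, r in enumerate(rows_b):
                new_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                new_b[k] += GAP
    return new_a, new_b


def progressive_msa(seqs: SequenceSet, s: ScoringScheme = ScoringScheme()) -> Msa:
    """Progressive multiple alignment along a neighbor-joining guide tree.

    Pairwise p-distances from global alignments feed neighbor joining; the
    resulting guide tree is traversed leaf-to-root, merging sub-alignments
    by profile-profile global alignment.  Rows come back in input order and
    removing the gaps of any row reproduces the input sequence exactly.
    """
    from .phylo import neighbor_joining  # local import avoids a module cycle
    from skbio import DistanceMatrix

    seq_list = list(seqs)
    n = len(seq_list)
    if n < 2:
        raise AlignError("progressive_msa needs at least 2 sequences")
    if n == 2:
        aln = global_align(seq_list[0], seq_list[1], s)
        return Msa([(seq_list[0].id, aln.aligned_a), (seq_list[1].id, aln.aligned_b)])
    ids = [q.id for q in seq_list]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_p_distance(seq_list[i], seq_list[j], s)
            dm[i, j] = dm[j, i] = d
    tree = neighbor_joining(DistanceMatrix(dm, ids))

    by_id = {q.id: q for q in seq_list}

    def merge(node) -> Tuple[List[str], List[str]]:
        """Returns (row ids, gapped rows) for the subtree."""
        if node.is_tip():
            return [node.name], [by_id[node.name].residues]
        child_alns = [merge(c) for c in node.children]
        ids_acc, rows_acc = child_alns[0]
        for cid, crows in child_alns[1:]:
            rows_a, rows_b = _profile_align(rows_acc, crows, s)
            ids_acc = ids_acc + cid
            rows_acc = rows_a + rows_b
        return ids_acc, rows_acc

    row_ids, rows = merge(tree)
    order = {i: k for k, i in enumerate(row_ids)}
    return Msa([(i, rows[order[i]]) for i in ids])
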