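"""Signature-motif model, the built-in PB2SF-anchored motifs, scanner and classifier.

A signature motif is an anchored run of positions on the PB2SF 2-O-sulfatase
coordinate system.  Each position is *fixed* (one or two allowed residues
with a conservation weight), a *wildcard* ``X`` (any residue, consumes one
candidate position), or *optional* ``(X,0)`` (any residue or absent).  Five
built-in motifs (A-E) encode the conserved regions of the bacterial
Delta-4,5-hexuronate-2-O-sulfatase family (SulfAtlas S1_9); motif B contains
the universal arylsulfatase core C/S-X-P-X-R whose Cys/Ser is the
formylglycine precursor.

The scanner slides each motif over a candidate, enumerating every start
offset and every optional-position inclusion mask, and reports the best
normalized score sum(w_i * [residue in allowed_i]) / sum(w_i).  A candidate
is called a predicted 2-O-sulfatase when the core motif is present inside
its motif-B match and at least 4 of the 5 motifs score >= 0.7 (both
configurable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence as TSeq, Tuple

import numpy as np

from .seqcore import Sequence

_KINDS = ("fixed", "wildcard", "optional")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPosition:
    ref_pos: int  # 1-based PB2SF coordinate
    kind: str = "fixed"
    allowed: str = ""  # 1-2 residues for fixed; empty otherwise
    weight: float = 0.0  # conservation fraction; 0 for wildcard/optional
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise MotifError(f"unknown position kind {self.kind!r}")
        if self.kind == "fixed":
            if not (1 <= len(self.allowed) <= 2):
                raise MotifError(f"fixed position {self.ref_pos} needs 1-2 allowed residues")
            if not (0.0 < self.weight <= 1.0):
                raise MotifError(f"fixed position {self.ref_pos} weight {self.weight} not in (0,1]")
        else:
            if self.allowed or self.weight != 0.0:
                raise MotifError(f"{self.kind} position {self.ref_pos} must have no residues/weight")


@dataclass(frozen=True)
class SignatureMotif:
    name: str
    positions: Tuple[MotifPosition, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifError(f"motif {self.name!r} is empty")
        refs = [p.ref_pos for p in self.positions]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise MotifError(f"motif {self.name!r} positions are not strictly increasing")
        if self.positions[0].kind != "fixed" or self.positions[-1].kind != "fixed":
            raise MotifError(f"motif {self.name!r} must start and end on fixed positions")

    @property
    def anchor(self) -> int:
        return self.positions[0].ref_pos

    @property
    def weight_sum(self) -> float:
        return sum(p.weight for p in self.positions if p.kind == "fixed")

    @property
    def n_fixed(self) -> int:
        return sum(1 for p in self.positions if p.kind == "fixed")

    @property
    def optional_positions(self) -> Tuple[int, ...]:
        return tuple(p.ref_pos for p in self.positions if p.kind == "optional")

    def consensus(self, fill: str = "A") -> str:
        """Consensus string with wildcards/optionals filled with ``fill``."""
        return "".join(p.allowed[0] if p.kind == "fixed" else fill for p in self.positions)


@dataclass(frozen=True)
class MotifMatch:
    """Best placement of one motif on a candidate."""

    motif: str
    start: int  # 1-based start in the candidate, 0 when unmatchable
    included_optionals: Tuple[int, ...]  # ref_pos of optional positions consumed
    matched_count: int
    weighted_score: float
    normalized: float
    position_map: Dict[int, int] = field(default_factory=dict)  # ref_pos -> 1-based candidate pos
    matchable: bool = True


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Catalytic positions on the PB2SF coordinate system.

    Asp52 and His310 are essential (their mutants are inactive); Asn113,
    Lys141, His143 and His205 mutants retain only feeble activity; position
    92 is the Cys (FGly precursor) and accepts Ser, the family core motif
    allowing both.
    """

    positions: Tuple[Tuple[int, str], ...] = (
        (52, "D"), (92, "CS"), (113, "N"), (141, "K"), (143, "H"), (205, "H"), (310, "H"),
    )


@dataclass(frozen=True)
class CatalyticSite:
    ref_pos: int
    expected: str
    candidate_pos: Optional[int]  # None when the position is absent in the candidate
    observed: Optional[str]
    status: str  # "match" | "mismatch" | "absent"


@dataclass(frozen=True)
class ClassificationReport:
    candidate_id: str
    matches: Tuple[MotifMatch, ...]
    core_motif_present: bool
    n_passing: int
    pass_threshold: float
    quorum: int
    catalytic: Tuple[CatalyticSite, ...] = ()
    predicted: bool = False


# ---------------------------------------------------------------------------
# built-ins and motif file I/O


def builtin_pb2sf_motifs() -> List[SignatureMotif]:
    """The five published signature motifs (A-E) on PB2SF coordinates."""
    with resources.files("sulfsig.data").joinpath("pb2sf_motifs.tsv").open() as fh:
        return _parse_motif_lines(fh)


def read_motifs(path) -> List[SignatureMotif]:
    with open(path) as fh:
        return _parse_motif_lines(fh)


def _parse_motif_lines(fh: Iterable[str]) -> List[SignatureMotif]:
    by_name: Dict[str, List[MotifPosition]] = {}
    order: List[str] = []
    for lineno, line in enumerate(fh, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise MotifError(f"line {lineno}: expected >=5 tab-separated fields")
        name, ref_pos, kind, allowed, weight = parts[:5]
        note = parts[5] if len(parts) > 5 else ""
        try:
            pos = MotifPosition(
                ref_pos=int(ref_pos),
                kind=kind,
                allowed="" if allowed == "." else allowed,
                weight=float(weight),
                note=note,
            )
        except (MotifError, ValueError) as exc:
            raise MotifError(f"line {lineno}: {exc}") from exc
        if name not in by_name:
            by_name[name] = []
            order.append(name)
        by_name[name].append(pos)
    return [SignatureMotif(name=n, positions=tuple(by_name[n])) for n in order]


def write_motifs(motifs: TSeq[SignatureMotif], path) -> None:
    with open(path, "w") as fh:
        fh.write("# motif\tref_pos\tkind\tallowed\tweight\tnote\n")
        for m in motifs:
            for p in m.positions:
                fh.write(
                    f"{m.name}\t{p.ref_pos}\t{p.kind}\t{p.allowed or '.'}"
                    f"\t{p.weight:g}\t{p.note}\n"
                )


# ---------------------------------------------------------------------------
# scanning


def _scan_one(candidate: str, motif: SignatureMotif) -> MotifMatch:
    """Best placement of one motif: every start, every optional mask.

    Ties resolve to the highest score, then the smallest start, then the
    fewest included optionals (argmax picks the smallest start within a
    mask).
    """
    enc = np.frombuffer(candidate.encode("ascii"), dtype=np.uint8)
    n = len(candidate)
    opts = [i for i, p in enumerate(motif.positions) if p.kind == "optional"]
    wsum = motif.weight_sum
    best: Optional[Tuple[float, int, int, Tuple[int, ...], float, int]] = None
    any_fit = False
    for k in range(len(opts) + 1):
        for included in itertools.combinations(opts, k):
            incl = set(included)
            # pattern offsets for each kept motif position
            offsets: List[Tuple[int, MotifPosition]] = []
            off = 0
            for i, p in enumerate(motif.positions):
                if p.kind == "optional" and i not in incl:
                    continue
                offsets.append((off, p))
                off += 1
            span = off
            if span > n:
                continue
            any_fit = True
            n_starts = n - span + 1
            scores = np.zeros(n_starts)
            matched = np.zeros(n_starts, dtype=int)
            starts = np.arange(n_starts)
            for off, p in offsets:
                if p.kind != "fixed":
                    continue
                window = enc[starts + off]
                hit = window == ord(p.allowed[0])
                if len(p.allowed) > 1:
                    hit |= window == ord(p.allowed[1])
                scores += p.weight * hit
                matched += hit
            s = int(np.argmax(scores))
            norm = scores[s] / wsum
            key = (-round(norm, 12), s, k)
            if best is None or key < best[:3]:
                best = (key[0], s, k, tuple(motif.positions[i].ref_pos for i in included),
                        float(scores[s]), int(matched[s]))
                best_map = {p.ref_pos: s + off + 1 for off, p in offsets}
    if best is None:
        return MotifMatch(
            motif=motif.name, start=0, included_optionals=(), matched_count=0,
            weighted_score=0.0, normalized=0.0, matchable=False,
        )
    _, s, k, included_refs, wscore, mcount = best
    return MotifMatch(
        motif=motif.name,
        start=s + 1,
        included_optionals=included_refs,
        matched_count=mcount,
        weighted_score=wscore,
        normalized=wscore / wsum,
        position_map=best_map,
        matchable=True,
    )


def scan_sequence(
    candidate: Sequence,
    motifs: TSeq[SignatureMotif],
    pass_threshold: float = 0.7,
) -> List[MotifMatch]:
    """Scan a candidate protein against each motif; one best match per motif.

    A motif longer than the candidate is reported unmatchable with score 0.
    ``pass_threshold`` is not applied here (matches carry their normalized
    scores); it is the classifier's decision boundary.
    """
    if candidate.alphabet != "protein":
        raise MotifError("scan_sequence requires a protein candidate")
    return [_scan_one(candidate.residues, m) for m in motifs]


# ---------------------------------------------------------------------------
# reference mapping and classification


def map_to_reference(candidate: Sequence, reference: Sequence) -> Dict[int, int]:
    """Map reference positions to candidate positions via global alignment.

    A reference position maps iff both rows are non-gap in the same column.
    Positions are 1-based; unmapped reference positions are absent.
    """
    from .align import ScoringScheme, global_align

    aln = global_align(candidate, reference, ScoringScheme())
    out: Dict[int, int] = {}
    ci = ri = 0
    for ca, ra in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            ci += 1
        if ra != "-":
            ri += 1
            if ca != "-":
                out[ri] = ci
    return out


def check_catalytic_residues(
    candidate: Sequence,
    reference: Sequence,
    annotation: ReferenceAnnotation = ReferenceAnnotation(),
) -> List[CatalyticSite]:
    """Report presence of the annotated catalytic residues in a candidate."""
    cmap = map_to_reference(candidate, reference)
    out: List[CatalyticSite] = []
    for ref_pos, expected in annotation.positions:
        cpos = cmap.get(ref_pos)
        if cpos is None:
            out.append(CatalyticSite(ref_pos, expected, None, None, "absent"))
        else:
            obs = candidate.residues[cpos - 1]
            status = "match" if obs in expected else "mismatch"
            out.append(CatalyticSite(ref_pos, expected, cpos, obs, status))
    return out


#: ref positions of the universal arylsulfatase core C/S-X-P-X-R inside motif B
CORE_MOTIF_CHECKS: Tuple[Tuple[int, str], ...] = ((92, "CS"), (94, "P"), (96, "R"))


def _core_motif_present(candidate: str, motif_b_match: MotifMatch) -> bool:
    if not motif_b_match.matchable:
        return False
    for ref_pos, allowed in CORE_MOTIF_CHECKS:
        cpos = motif_b_match.position_map.get(ref_pos)
        if cpos is None or candidate[cpos - 1] not in allowed:
            return False
    return True


def classify_candidate(
    candidate: Sequence,
    motifs: Optional[TSeq[SignatureMotif]] = None,
    reference: Optional[Sequence] = None,
    annotation: ReferenceAnnotation = ReferenceAnnotation(),
    pass_threshold: float = 0.7,
    quorum: int = 4,
) -> ClassificationReport:
    """Classify a candidate as predicted 2-O-sulfatase or not.

    Verdict: the core motif C/S-X-P-X-R must be present inside the motif-B
    match AND at least ``quorum`` of the motifs must reach
    ``pass_threshold``.  Catalytic residues are reported (when a reference
    is supplied) but do not enter the verdict.
    """
    motifs = list(motifs) if motifs is not None else builtin_pb2sf_motifs()
    matches = scan_sequence(candidate, motifs, pass_threshold)
    by_name = {m.motif: m for m in matches}
    core = False
    if "B" in by_name:
        core = _core_motif_present(candidate.residues, by_name["B"])
    n_passing = sum(1 for m in matches if m.matchable and m.normalized >= pass_threshold)
    catalytic: Tuple[CatalyticSite, ...] = ()
    if reference is not None:
        catalytic = tuple(check_catalytic_residues(candidate, reference, annotation))
    return ClassificationReport(
        candidate_id=candidate.id,
        matches=tuple(matches),
        core_motif_present=core,
        n_passing=n_passing,
        pass_threshold=pass_threshold,
        quorum=quorum,
        catalytic=catalytic,
        predicted=core and n_passing >= quorum,
    )
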