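"""Synthetic protein families with planted signature motifs and truth tables.

Families are generated under an independent-mutant (star-phylogeny) model: a
random ancestor carries the motif consensus at chosen offsets, and each
family member is an independent mutant of that ancestor.  At motif fixed
positions the consensus residue is kept with probability equal to the
position's conservation target (else substituted uniformly among the 19
alternatives); background positions substitute with a flat background
probability; optional motif positions are deleted with one minus their
presence probability; background indels are symmetric single-residue
insertions/deletions.  Column-wise conservation statistics therefore have
exact binomial expectations, which is what makes the generator a usable
oracle for the conservation and scanner stages.  Multi-family datasets give
each family its own ancestor derived from a shared base sequence at a
controlled divergence, emulating a family of interest plus outgroup
families for phylogeny tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as TSeq, Tuple

import numpy as np

from .seqcore import Sequence, SequenceSet
from .signatures import SignatureMotif

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedMotifSpec:
    """A motif to embed in a family's ancestor.

    ``offset`` is the 0-based ancestor position of the motif's first
    position.  Conservation targets default to the motif's own weights;
    wildcard positions evolve as background.
    """

    motif: SignatureMotif
    offset: int
    conservation_targets: Optional[Dict[int, float]] = None  # ref_pos -> target
    optional_presence: float = 1.0

    def target(self, ref_pos: int, default: float) -> float:
        if self.conservation_targets is None:
            return default
        return self.conservation_targets.get(ref_pos, default)

    @property
    def span(self) -> int:
        return len(self.motif.positions)


@dataclass(frozen=True)
class FamilySpec:
    label: str
    n_sequences: int
    ancestor_length: int
    #: per-position substitution probability outside conserved motif positions;
    #: the default leaves ~33% background identity, i.e. divergent homologs
    #: whose background columns sit well below the conservation threshold
    background_substitution: float = 0.7
    background_indel: float = 0.0
    planted_motifs: Tuple[PlantedMotifSpec, ...] = ()
    positive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise SynthError("n_sequences must be >= 2")
        for p in (self.background_substitution, self.background_indel):
            if not (0.0 <= p < 1.0):
                raise SynthError("probabilities must lie in [0, 1)")
        spans = sorted((m.offset, m.offset + m.span) for m in self.planted_motifs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise SynthError("planted motif placements overlap")
        for m in self.planted_motifs:
            if m.offset < 0 or m.offset + m.span > self.ancestor_length:
                raise SynthError(f"motif {m.motif.name!r} does not fit in the ancestor")


@dataclass
class MotifInstance:
    seq_id: str
    motif: str
    positions: Dict[int, int]  # ref_pos -> 1-based position in the emitted sequence
    residues: Dict[int, str]  # ref_pos -> residue actually emitted


@dataclass
class TruthTable:
    """Generator ground truth: labels, planted positions, realized conservation."""

    families: Dict[str, str] = field(default_factory=dict)  # seq_id -> family label
    positives: Dict[str, bool] = field(default_factory=dict)  # seq_id -> positive flag
    motif_instances: List[MotifInstance] = field(default_factory=list)
    # (family, motif, ref_pos) -> realized conservation among that family's sequences
    realized_conservation: Dict[Tuple[str, str, int], float] = field(default_factory=dict)

    def merge(self, other: "TruthTable") -> None:
        overlap = set(self.families) & set(other.families)
        if overlap:
            raise SynthError(f"duplicate sequence ids across families: {sorted(overlap)[:3]}")
        self.families.update(other.families)
        self.positives.update(other.positives)
        self.motif_instances.extend(other.motif_instances)
        self.realized_conservation.update(other.realized_conservation)


def _random_protein(rng: np.random.Generator, length: int) -> List[str]:
    return [AA20[i] for i in rng.integers(0, 20, size=length)]


def _substitute(rng: np.random.Generator, residue: str) -> str:
    alternatives = AA20.replace(residue, "") if residue in AA20 else AA20
    return alternatives[rng.integers(0, len(alternatives))]


def _plant_consensus(rng: np.random.Generator, ancestor: List[str], spec: FamilySpec) -> None:
    for pm in spec.planted_motifs:
        for k, pos in enumerate(pm.motif.positions):
            if pos.kind == "fixed":
                ancestor[pm.offset + k] = pos.allowed[0]


def generate_family(
    spec: FamilySpec, ancestor: Optional[List[str]] = None
) -> Tuple[SequenceSet, TruthTable]:
    """Generate one family and its truth table; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    if ancestor is None:
        ancestor = _random_protein(rng, spec.ancestor_length)
    else:
        ancestor = list(ancestor)
        if len(ancestor) != spec.ancestor_length:
            raise SynthError("ancestor length does not match the spec")
    _plant_consensus(rng, ancestor, spec)

    # classify ancestor positions
    kind = ["bg"] * spec.ancestor_length  # bg | fixed | wildcard | optional
    meta: Dict[int, Tuple[PlantedMotifSpec, object]] = {}
    for pm in spec.planted_motifs:
        for k, pos in enumerate(pm.motif.positions):
            idx = pm.offset + k
            kind[idx] = pos.kind if pos.kind != "fixed" else "fixed"
            meta[idx] = (pm, pos)

    truth = TruthTable()
    seqs = SequenceSet()
    keep_counts: Dict[Tuple[str, int], int] = {}  # (motif name, ref_pos) -> consensus kept
    for si in range(spec.n_sequences):
        seq_id = f"{spec.label}_{si:03d}"
        chars: List[str] = []
        src_pos: List[int] = []  # ancestor index per emitted char, -1 for insertions
        for idx, anc_res in enumerate(ancestor):
            if kind[idx] == "optional":
                pm, _pos = meta[idx]
                if rng.random() >= pm.optional_presence:
                    continue  # optional position absent in this sequence
                res = anc_res if rng.random() >= spec.background_substitution else _substitute(rng, anc_res)
            elif kind[idx] == "fixed":
                pm, pos = meta[idx]
                target = pm.target(pos.ref_pos, pos.weight)
                if rng.random() < target:
                    res = anc_res
                    keep_counts[(pm.motif.name, pos.ref_pos)] = (
                        keep_counts.get((pm.motif.name, pos.ref_pos), 0) + 1
                    )
                else:
                    res = _substitute(rng, anc_res)
            else:  # bg or wildcard: background evolution
                if spec.background_indel > 0.0 and rng.random() < spec.background_indel / 2.0:
                    continue  # deletion
                res = anc_res if rng.random() >= spec.background_substitution else _substitute(rng, anc_res)
            chars.append(res)
            src_pos.append(idx)
            if (
                kind[idx] in ("bg", "wildcard")
                and spec.background_indel > 0.0
                and rng.random() < spec.background_indel / 2.0
            ):
                chars.append(AA20[rng.integers(0, 20)])
                src_pos.append(-1)
        residues = "".join(chars)
        seqs.add(Sequence(id=seq_id, residues=residues, alphabet="protein"))
        truth.families[seq_id] = spec.label
        truth.positives[seq_id] = spec.positive
        anc_to_emit = {a: e + 1 for e, a in enumerate(src_pos) if a >= 0}
        for pm in spec.planted_motifs:
            positions: Dict[int, int] = {}
            emitted: Dict[int, str] = {}
            for k, pos in enumerate(pm.motif.positions):
                idx = pm.offset + k
                if idx in anc_to_emit:
                    positions[pos.ref_pos] = anc_to_emit[idx]
                    emitted[pos.ref_pos] = residues[anc_to_emit[idx] - 1]
            truth.motif_instances.append(
                MotifInstance(seq_id=seq_id, motif=pm.motif.name, positions=positions, residues=emitted)
            )
    for pm in spec.planted_motifs:
        for pos in pm.motif.positions:
            if pos.kind != "fixed":
                continue
            kept = keep_counts.get((pm.motif.name, pos.ref_pos), 0)
            truth.realized_conservation[(spec.label, pm.motif.name, pos.ref_pos)] = (
                kept / spec.n_sequences
            )
    return seqs, truth


def generate_dataset(
    family_specs: TSeq[FamilySpec],
    inter_family_divergence: float = 0.5,
    seed: int = 0,
) -> Tuple[SequenceSet, TruthTable]:
    """Generate several families with ancestors at a controlled divergence.

    All family ancestors derive from one shared base sequence; each is an
    independent mutant with per-site substitution probability
    ``inter_family_divergence / 2`` so that the expected pairwise ancestor
    p-distance is approximately the requested divergence.  Ancestors must
    share a common length (the max of the specs); shorter specs are not
    supported in multi-family mode.
    """
    labels = [fs.label for fs in family_specs]
    if len(set(labels)) != len(labels):
        raise SynthError("family labels must be distinct")
    if not family_specs:
        return SequenceSet(), TruthTable()
    lengths = {fs.ancestor_length for fs in family_specs}
    if len(lengths) != 1:
        raise SynthError("all families in a dataset must share the ancestor length")
    length = lengths.pop()
    rng = np.random.default_rng(seed)
    base = _random_protein(rng, length)
    q = min(max(inter_family_divergence / 2.0, 0.0), 0.95)
    all_seqs = SequenceSet()
    truth = TruthTable()
    for fs in family_specs:
        anc = [c if rng.random() >= q else _substitute(rng, c) for c in base]
        fam_seqs, fam_truth = generate_family(fs, ancestor=anc)
        for s in fam_seqs:
            all_seqs.add(s)
        truth.merge(fam_truth)
    return all_seqs, truth


# ---------------------------------------------------------------------------
# truth-table I/O


def write_truth(truth: TruthTable, path) -> None:
    """Two-section TSV: sequence rows then motif-instance rows.

    Realized conservation is carried in ``#conservation`` comment lines so
    that data rows count exactly sequences + motif instances.
    """
    with open(path, "w") as fh:
        fh.write("# section: sequences (seq\tid\tfamily\tpositive)\n")
        fh.write("# section: motifs (motif\tid\tname\tref:pos:res,...)\n")
        for (fam, motif, ref_pos), c in sorted(truth.realized_conservation.items()):
            fh.write(f"#conservation\t{fam}\t{motif}\t{ref_pos}\t{c:.6f}\n")
        for seq_id, fam in truth.families.items():
            fh.write(f"seq\t{seq_id}\t{fam}\t{int(truth.positives[seq_id])}\n")
        for mi in truth.motif_instances:
            cells = ",".join(
                f"{rp}:{mi.positions[rp]}:{mi.residues[rp]}" for rp in sorted(mi.positions)
            )
            fh.write(f"motif\t{mi.seq_id}\t{mi.motif}\t{cells}\n")


def read_truth(path) -> TruthTable:
    truth = TruthTable()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#conservation\t"):
                _, fam, motif, ref_pos, c = line.split("\t")
                truth.realized_conservation[(fam, motif, int(ref_pos))] = float(c)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "seq":
                _, seq_id, fam, pos_flag = parts
                truth.families[seq_id] = fam
                truth.positives[seq_id] = bool(int(pos_flag))
            elif parts[0] == "motif":
                _, seq_id, name, cells = (parts + [""])[:4]
                positions: Dict[int, int] = {}
                residues: Dict[int, str] = {}
                if cells:
                    for cell in cells.split(","):
                        rp, pos, res = cell.split(":")
                        positions[int(rp)] = int(pos)
                        residues[int(rp)] = res
                truth.motif_instances.append(
                    MotifInstance(seq_id=seq_id, motif=name, positions=positions, residues=residues)
                )
    return truth
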