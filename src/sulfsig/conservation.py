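"""Column-wise conservation statistics over a multiple alignment.

Conservation of a column is the fraction of rows carrying the modal residue,
with *all* rows (including gapped ones) in the denominator, so that a weight
of 1.0 means literally universal presence across the family.  Logo stack
heights use the standard gap-excluded convention, log2(20) minus the Shannon
entropy of the renormalized residue frequencies; the two statistics are
reported side by side.  Signature regions are maximal runs of conserved
columns with short wildcard interruptions, the machine analogue of reading
conserved blocks off a family alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence as TSeq, Tuple

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import Sequence, SequenceSet
from .signatures import MotifPosition, SignatureMotif

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
LOG2_20 = math.log2(20.0)


class MsaError(ValueError):
    pass


class Msa:
    """Ordered gapped rows of equal length with unique ids."""

    def __init__(self, rows: TSeq[Tuple[str, str]]) -> None:
        if not rows:
            raise MsaError("alignment has no rows")
        self.ids: List[str] = [r[0] for r in rows]
        self.rows: List[str] = [r[1].upper() for r in rows]
        if len(set(self.ids)) != len(self.ids):
            raise MsaError("row ids are not unique")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise MsaError("rows have unequal lengths")
        for j in range(n):
            if all(r[j] == GAP for r in self.rows):
                raise MsaError(f"column {j + 1} is all gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        """0-based column as a string over rows."""
        return "".join(r[j] for r in self.rows)

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(
            [Sequence(id=i, residues=self.ungapped(i), alphabet="protein") for i in self.ids]
        )

    # --- I/O -------------------------------------------------------------

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Msa":
        """Read an aligned FASTA ("fasta") or Clustal ("clustal") file."""
        aln = AlignIO.read(str(path), fmt)
        return cls([(rec.id, str(rec.seq)) for rec in aln])

    def write(self, path, fmt: str = "fasta") -> None:
        aln = MultipleSeqAlignment(
            [SeqRecord(Seq(r), id=i, description="") for i, r in zip(self.ids, self.rows)]
        )
        AlignIO.write(aln, str(path), fmt)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column residue statistics of an alignment."""

    column: int  # 1-based alignment column
    counts: Dict[str, int]  # residue -> count (no gap entry)
    gap_count: int
    n_rows: int
    dominant: str
    conservation: float  # dominant count / n_rows (gap-included denominator)
    runner_up: Optional[str]
    runner_up_fraction: float
    gap_fraction: float
    ref_position: Optional[int]  # 1-based position in the reference row


@dataclass(frozen=True)
class ConservationProfile:
    reference_id: str
    columns: Tuple[ColumnProfile, ...]

    def __len__(self) -> int:
        return len(self.columns)


def build_profile(msa: Msa, reference_id: str) -> ConservationProfile:
    """Profile every column, mapping columns to reference coordinates.

    ``ref_position`` counts non-gap reference characters left to right and is
    absent (None) where the reference row is gapped.
    """
    if reference_id not in msa.ids:
        raise MsaError(f"reference id {reference_id!r} not in alignment")
    ref_row = msa.row(reference_id)
    cols: List[ColumnProfile] = []
    ref_pos = 0
    n = msa.n_rows
    for j in range(msa.n_columns):
        col = msa.column(j)
        gap_count = col.count(GAP)
        counts: Dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        # deterministic tie-break: count desc then residue asc
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        dominant, dom_count = ranked[0]
        runner_up, ru_count = (ranked[1] if len(ranked) > 1 else (None, 0))
        if ref_row[j] != GAP:
            ref_pos += 1
            rp: Optional[int] = ref_pos
        else:
            rp = None
        cols.append(
            ColumnProfile(
                column=j + 1,
                counts=counts,
                gap_count=gap_count,
                n_rows=n,
                dominant=dominant,
                conservation=dom_count / n,
                runner_up=runner_up,
                runner_up_fraction=ru_count / n,
                gap_fraction=gap_count / n,
                ref_position=rp,
            )
        )
    return ConservationProfile(reference_id=reference_id, columns=tuple(cols))


def information_content(col: ColumnProfile) -> float:
    """Logo stack height in bits: log2(20) - H(residue frequencies).

    Gaps are excluded and the residue frequencies renormalized; no
    small-sample correction is applied.
    """
    total = sum(col.counts.values())
    if total == 0:
        raise MsaError(f"column {col.column} is all gaps")
    h = 0.0
    for c in col.counts.values():
        p = c / total
        h -= p * math.log2(p)
    return LOG2_20 - h


def extract_signature_regions(
    profile: ConservationProfile,
    tau: float = 0.47,
    max_wildcard_run: int = 3,
    optional_gap_min: float = 0.5,
    min_conserved: int = 4,
) -> List[SignatureMotif]:
    """Extract signature motifs as runs of conserved columns.

    A region is a maximal run of columns starting and ending at columns with
    conservation >= ``tau``, containing at least ``min_conserved`` such
    columns, with no interior stretch of more than ``max_wildcard_run``
    consecutive sub-tau columns.  Sub-tau interior columns become wildcards,
    or optional positions when their gap fraction reaches
    ``optional_gap_min``.  Conserved positions whose runner-up residue
    reaches 25% record a two-residue allowed set.  Columns where the
    reference row is gapped (insertions relative to the reference) are not
    part of the reference-anchored motif and are dropped.
    """
    cols = [c for c in profile.columns if c.ref_position is not None]
    conserved = [c.conservation >= tau for c in cols]
    idx = [i for i, f in enumerate(conserved) if f]
    if not idx:
        return []

    groups: List[List[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i - groups[-1][-1] - 1 <= max_wildcard_run:
            groups[-1].append(i)
        else:
            groups.append([i])

    motifs: List[SignatureMotif] = []
    label = 0
    for g in groups:
        if len(g) < min_conserved:
            continue
        positions: List[MotifPosition] = []
        for i in range(g[0], g[-1] + 1):
            c = cols[i]
            assert c.ref_position is not None
            if conserved[i]:
                allowed = c.dominant
                if c.runner_up is not None and c.runner_up_fraction >= 0.25:
                    allowed = "".join(sorted(c.dominant + c.runner_up))
                positions.append(
                    MotifPosition(
                        ref_pos=c.ref_position, kind="fixed", allowed=allowed,
                        weight=c.conservation,
                    )
                )
            elif c.gap_fraction >= optional_gap_min:
                positions.append(MotifPosition(ref_pos=c.ref_position, kind="optional"))
            else:
                positions.append(MotifPosition(ref_pos=c.ref_position, kind="wildcard"))
        label += 1
        motifs.append(SignatureMotif(name=f"region_{label}", positions=tuple(positions)))
    return motifs


def export_logo_table(profile: ConservationProfile, path) -> None:
    """Write the per-column logo table as TSV.

    One row per alignment column: column, ref_position, the 20 residue
    frequencies on the gap-included denominator (so they sum to
    1 - gap_fraction), gap_fraction, conservation, and the gap-excluded
    information content in bits.
    """
    with open(path, "w") as fh:
        header = ["column", "ref_position"] + list(AA20) + [
            "gap_fraction", "conservation", "information_bits",
        ]
        fh.write("\t".join(header) + "\n")
        for c in profile.columns:
            freqs = [c.counts.get(a, 0) / c.n_rows for a in AA20]
            row = [str(c.column), "" if c.ref_position is None else str(c.ref_position)]
            row += [f"{f:.6f}" for f in freqs]
            row += [f"{c.gap_fraction:.6f}", f"{c.conservation:.6f}", f"{information_content(c):.6f}"]
            fh.write("\t".join(row) + "\n")
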