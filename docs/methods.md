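# Methods

This note records the models, conventions and numerical choices behind
`sulfsig`, and what the synthetic benchmarks do and do not demonstrate.

## Sequence-level properties

ORFs are translated under the bacterial genetic code (NCBI table 11); the
initiator codon is always rendered as Met, a trailing stop codon is
dropped, and an internal stop is an error. GC content is
`100·(G+C)/(A+C+G+T)` with ambiguous N excluded from both numerator and
denominator, reported to one decimal. Molecular weight uses average
(not monoisotopic) residue masses plus one water (18.0153 Da), matching the
convention of the common web calculators against which published values are
quoted. The isoelectric point solves `charge(pH) = 0` by bisection on
[0, 14] with the Bjellqvist pKa set (N/C termini plus D, E, C, Y, H, K, R
side chains); the returned pH carries a net charge below 0.01 elementary
charge. Duplicate removal is exact full-length string equality after
uppercasing — near-identical sequences are deliberately retained — and the
first occurrence wins, which makes the operation deterministic and
idempotent.

## Pairwise alignment and homolog screening

Global (Needleman–Wunsch, end gaps scored) and local (Smith–Waterman)
alignment use BLOSUM62 with BLAST-style affine gaps: a gap of length *k*
costs `open + k·extend`, defaults open 11, extend 1. Percent identity is
identities over **all** alignment columns (gaps in the denominator, the
BLAST convention; configurable), and query cover is the aligned fraction of
the query. A local alignment whose optimal score is ≤ 0 (e.g. disjoint
residue compositions) is reported as no hit. Homolog screening keeps, per
query, the up-to-`top_n` (default 100) highest-identity subjects with
identity **strictly** above `min_identity` (default 40%), ties broken by
subject id so the output is independent of database order; an optional
query-cover floor exists but is off by default because the screening
procedure being emulated states only the identity cutoff. The
Smith–Waterman search is exhaustive, not heuristic: there is no k-mer
seeding or E-value model, so the screen is exact but not meant for more
than a few thousand subjects.

Scores are computed by Biopython's `PairwiseAligner`; its traceback
tie-break differs from a fixed diagonal-first rule but is deterministic,
which is the property the pipeline contracts (byte-identical reruns).
Optimal scores — the quantity all downstream statistics depend on — are
verified against exhaustive enumeration of alignment paths.

## Progressive multiple alignment

The guide tree is neighbor joining on pairwise p-distances taken from
global alignments. Sub-alignments are merged leaf-to-root by
profile–profile global alignment (three-state Gotoh) with sum-of-pairs
scoring: the score of pairing two columns is the count-weighted sum of
substitution scores over their residues, and gap open/extend costs scale
with the number of sequence pairs crossing the gap, keeping substitution
and gap terms on the same scale. Two sequences reduce exactly to the
pairwise global alignment. There is no iterative refinement; externally
computed alignments (aligned FASTA or Clustal) are accepted wherever an
alignment is consumed, which is the intended route for users who prefer a
dedicated aligner.

## Conservation, logos, and signature-region extraction

Conservation of a column is the modal-residue count divided by **all** rows
(gapped rows included), so a weight of 1.0 means literally universal
presence; a gap-excluded mode would inflate columns that are simply absent
in part of the family. The logo statistic is `log2(20) − H` over
gap-excluded, renormalized frequencies, with no small-sample correction;
the two statistics answer different questions and are exported side by
side in the logo table.

Signature regions are maximal runs of columns with conservation ≥ τ
containing at least `min_conserved = 4` such columns, allowing interior
interruptions of at most `max_wildcard_run = 3` consecutive sub-τ columns
(which become wildcards, or optional positions when their gap fraction
reaches `optional_gap_min = 0.5`). τ defaults to 0.47 because the weakest
position in the built-in motif set carries 47% conservation; all four knobs
are parameters, not constants. A conserved position whose runner-up
residue reaches 25% records a two-residue allowed set (this is what
produces Cys/Ser at the FGly site). Columns where the chosen reference row
is gapped are insertions relative to the reference coordinate system and
are dropped from the extracted motif. Extracted regions always begin and
end on conserved columns.

A structural consequence worth knowing: a region whose interior contains a
position conserved at almost exactly τ (the built-in motif B has one at
0.50) can split in a finite sample when that position realizes below τ and
the sub-τ run behind it exceeds `max_wildcard_run`; trailing conserved
columns then fail `min_conserved` and are not reported. At 200 sequences
this happens in a noticeable fraction of random draws. It is the correct
output of the stated rule, not noise in the implementation.

## Motif model, scanner, classifier

A motif position is fixed (1–2 allowed residues, conservation weight in
(0, 1]), wildcard (consumes one residue, no constraint), or optional
(consumes zero or one). The five built-in motifs A–E live in one data file
on reference (PB2SF) coordinates 44–52, 86–102, 194–208, 301–315, 417–446;
the file flags the FGly-precursor site (92, C/S, encoded with weight 1.00
since no percentage is published for it) and one glutamate whose published
index is inconsistent with its neighbors (encoded at 441, flagged
`printed_as_E444` rather than silently renumbered).

Scanning is ungapped within a motif except at declared optional positions:
every start offset and every optional-inclusion mask is evaluated, and the
best normalized score `Σ wᵢ·[match] / Σ wᵢ` is kept (ties: smallest start,
then fewest included optionals). Insertions *between* motifs are therefore
unconstrained, matching the observation that inter-motif spacing varies
across the family while the motifs themselves are short contiguous blocks.
The classifier calls a candidate a predicted 2-*O*-sulfatase iff the core
C/S-X-P-X-R is present inside the motif-B match AND at least `quorum = 4`
of the 5 motifs reach `pass_threshold = 0.7`; both knobs are configurable.
The seven annotated catalytic positions (D52, C/S92, N113, K141, H143,
H205, H310) are reported via a global-alignment coordinate map but do not
enter the verdict, since three of them lie outside all five motifs.

## Phylogeny

Distances are p-distances under pairwise deletion (mismatches over shared
non-gap columns); no multiple-hit correction is applied by default because
the trees being emulated are drawn on a substitutions-per-site scale with
no model stated. Neighbor joining follows the Saitou–Nei Q-criterion;
Q-ties break on the lexicographically smallest label pair and negative
branch lengths are clamped to zero without redistribution — the simplest
defensible convention, and one that keeps trees identical across
platforms. On additive matrices the reconstruction is exact to machine
precision (the main correctness oracle). Bootstrap support of an internal
edge is the percentage of column-resampled replicates whose NJ tree
contains the same unrooted bipartition, counted by canonicalized leaf
sets; supports are written as internal-node labels in Newick. Clade
membership roots the tree on the outgroup attachment edge
(`root_by_outgroup`); a non-monophyletic outgroup downgrades to rooting at
the outgroup MRCA with a warning. A candidate is inside iff it descends
from the MRCA of the family label set — note that the family set must span
the clade being asked about: in the pipeline it is the references plus the
screened candidates, not the references alone (whose MRCA would be their
own cherry).

## Synthetic families

`generate_family` uses an independent-mutant (star-phylogeny) model: one
random ancestor (uniform over 20 residues) carries the motif consensus;
each family member keeps a motif fixed position with probability equal to
its conservation target (default: the motif's published weight) and
otherwise substitutes uniformly among the 19 alternatives; background and
wildcard positions substitute with probability `background_substitution`
(default 0.7, leaving ~33% background identity — divergent homologs whose
background columns sit well below τ); optional positions are deleted with
one minus their presence probability; background indels are symmetric
single-residue events. Independence across sequences makes every column a
binomial sample, so conservation recovery has exact 3σ error bars — that
is the point of the model. `generate_dataset` derives each family's
ancestor from a shared base with per-site substitution probability
`divergence/2`, giving the requested expected pairwise ancestor distance;
within-dataset evolution remains star-shaped.

What the generator does **not** emulate: tree-structured within-family
evolution, residue exchangeability (substitutions are uniform, not
BLOSUM-distributed), rate heterogeneity, domain-level indels, or
compositional bias. Passing the synthetic benchmarks therefore shows that
the machinery is correct under the stated statistical model, not that the
thresholds are optimal for real proteomes; on real data the pipeline
additionally accepts externally computed alignments and user-supplied
motif files.

## Problem sizes and determinism

The bundled benchmarks use: 50 random additive matrices of 4–10 taxa for
the NJ oracle; 90 sampled sequence pairs (lengths ≤ 6 global, ≤ 4 local)
for the alignment oracle; one 200-sequence planted family for conservation
recovery; 200 random 500-mers for the scanner null; and a 3 × 10-sequence
three-family dataset with 100 bootstrap replicates for clade
classification. These sizes give stable statistics (binomial error bars of
a few percent) while keeping the whole suite and the acceptance script in
the tens of seconds on one CPU. Every stochastic stage draws from a
`numpy` Generator seeded from a single configuration seed; stage-local
seeds are derived deterministically from it, and identical inputs plus an
identical seed reproduce reports byte for byte.
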