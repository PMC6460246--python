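import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_consensus_candidate, random_protein
from oracles import enumerate_best_motif_score
from sulfsig.seqcore import Sequence
from sulfsig.signatures import (
    MotifError,
    MotifPosition,
    SignatureMotif,
    check_catalytic_residues,
    classify_candidate,
    map_to_reference,
    read_motifs,
    scan_sequence,
    write_motifs,
)


class TestBuiltinMotifs:
    def test_five_motifs_with_expected_spans(self, motifs):
        assert [m.name for m in motifs] == ["A", "B", "C", "D", "E"]
        spans = {m.name: (m.anchor, m.positions[-1].ref_pos) for m in motifs}
        assert spans == {"A": (44, 52), "B": (86, 102), "C": (194, 208),
                         "D": (301, 315), "E": (417, 446)}

    def test_motif_a_terminal_positions(self, motifs):
        a = motifs[0]
        assert len(a.positions) == 9
        first, last = a.positions[0], a.positions[-1]
        assert (first.allowed, first.weight) == ("P", 0.70)
        assert (last.allowed, last.weight) == ("D", 1.00)

    def test_fgly_precursor_site_allows_cys_or_ser(self, motifs):
        b = next(m for m in motifs if m.name == "B")
        p92 = next(p for p in b.positions if p.ref_pos == 92)
        assert set(p92.allowed) == {"C", "S"}
        assert p92.note == "fgly_precursor"

    def test_catalytic_histidine_310_fully_conserved(self, motifs):
        d = next(m for m in motifs if m.name == "D")
        p310 = next(p for p in d.positions if p.ref_pos == 310)
        assert (p310.allowed, p310.weight) == ("H", 1.00)

    def test_motif_e_optional_positions(self, motifs):
        e = next(m for m in motifs if m.name == "E")
        assert e.optional_positions == (421, 427, 428)


class TestMotifIO:
    def test_round_trip_builtins(self, motifs, tmp_path):
        p = tmp_path / "motifs.tsv"
        write_motifs(motifs, p)
        assert read_motifs(p) == list(motifs)

    def test_weight_above_one_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("M\t1\tfixed\tA\t1.2\nM\t2\tfixed\tD\t0.5\n")
        with pytest.raises(MotifError):
            read_motifs(p)

    def test_non_increasing_positions_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("M\t5\tfixed\tA\t0.5\nM\t4\tfixed\tD\t0.5\n")
        with pytest.raises(MotifError):
            read_motifs(p)


class TestScanner:
    def test_consensus_control_scores_one_on_all_motifs(self, motifs, consensus_candidate):
        for mm in scan_sequence(consensus_candidate, motifs):
            assert mm.normalized == pytest.approx(1.0)

    def test_single_substitution_drops_by_its_weight_share(self, motifs, consensus_candidate):
        a = motifs[0]
        chars = list(consensus_candidate.residues)
        chars[52 - 1] = "A"  # ablate the catalytic aspartate consensus
        mutant = Sequence(id="d52a", residues="".join(chars))
        mm = scan_sequence(mutant, motifs)[0]
        assert mm.normalized == pytest.approx(1 - 1.00 / a.weight_sum)

    def test_score_monotone_in_number_of_mismatches(self, motifs, consensus_candidate):
        a = motifs[0]
        fixed_offsets = [k for k, p in enumerate(a.positions) if p.kind == "fixed"]
        prev = 1.0
        chars = list(consensus_candidate.residues)
        for k in fixed_offsets:
            chars[a.anchor - 1 + k] = "W" if chars[a.anchor - 1 + k] != "W" else "Y"
            score = scan_sequence(Sequence(id="mut", residues="".join(chars)), [a])[0].normalized
            assert score <= prev + 1e-9
            prev = score

    def test_normalized_score_bounds_and_perfection(self, motifs):
        rng = np.random.default_rng(5)
        for i in range(10):
            cand = random_protein(rng, 500, f"r{i}")
            for mm in scan_sequence(cand, motifs):
                assert 0.0 <= mm.normalized <= 1.0
                if mm.normalized == 1.0:
                    assert mm.matched_count == next(
                        m for m in motifs if m.name == mm.motif).n_fixed

    def test_short_candidate_reported_unmatchable(self, motifs):
        short = Sequence(id="short", residues="MKV")
        mm = scan_sequence(short, motifs)[0]
        assert not mm.matchable and mm.normalized == 0.0

    def test_result_independent_of_flanking_sequence(self, motifs, consensus_candidate):
        rng = np.random.default_rng(8)
        flank = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 40))
        extended = Sequence(id="ext", residues=flank + consensus_candidate.residues + flank)
        base = scan_sequence(consensus_candidate, motifs)
        ext = scan_sequence(extended, motifs)
        for b, e in zip(base, ext):
            assert e.normalized == pytest.approx(b.normalized)
            assert e.start == b.start + 40

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        motif = SignatureMotif(name="T", positions=(
            MotifPosition(1, "fixed", "P", 0.8),
            MotifPosition(2, "wildcard"),
            MotifPosition(3, "optional"),
            MotifPosition(4, "fixed", "DE", 0.6),
            MotifPosition(5, "fixed", "K", 1.0),
        ))
        for i in range(30):
            cand = random_protein(rng, int(rng.integers(5, 60)), f"c{i}")
            expected = enumerate_best_motif_score(cand.residues, motif)
            got = scan_sequence(cand, [motif])[0].normalized
            assert got == pytest.approx(expected, abs=1e-12)


class TestReferenceMapping:
    def test_identity_map_on_self(self):
        ref = Sequence(id="ref", residues="MKVLDHGEW")
        assert map_to_reference(ref, ref) == {i: i for i in range(1, 10)}

    def test_insertion_shifts_downstream_positions(self):
        ref = Sequence(id="ref", residues="MKVLDHGEW")
        cand = Sequence(id="c", residues="MKVLADHGEW")  # A inserted after position 4
        cmap = map_to_reference(cand, ref)
        assert cmap[4] == 4 and cmap[5] == 6 and cmap[9] == 10

    def test_deleted_position_is_absent(self):
        ref = Sequence(id="ref", residues="MKVLDHGEW")
        cand = Sequence(id="c", residues="MKVLHGEW")  # D deleted
        cmap = map_to_reference(cand, ref)
        assert 5 not in cmap
        assert cmap[6] == 5


class TestCatalyticResidues:
    def test_reference_matches_itself(self, consensus_candidate):
        sites = check_catalytic_residues(consensus_candidate, consensus_candidate)
        # positions 113/141/143 fall outside all motifs: the consensus control
        # carries filler there, so only motif-covered sites must match
        by_pos = {s.ref_pos: s for s in sites}
        for pos in (52, 92, 205, 310):
            assert by_pos[pos].status == "match"

    def test_substituted_catalytic_position_reported_mismatch(self, consensus_candidate):
        chars = list(consensus_candidate.residues)
        chars[52 - 1] = "A"
        mutant = Sequence(id="d52a", residues="".join(chars))
        sites = {s.ref_pos: s for s in check_catalytic_residues(mutant, consensus_candidate)}
        assert sites[52].status == "mismatch" and sites[52].observed == "A"
        assert sites[310].status == "match"

    def test_serine_accepted_at_fgly_site(self, consensus_candidate):
        chars = list(consensus_candidate.residues)
        chars[92 - 1] = "S"
        variant = Sequence(id="ser", residues="".join(chars))
        sites = {s.ref_pos: s for s in check_catalytic_residues(variant, consensus_candidate)}
        assert sites[92].status == "match"


class TestClassifier:
    def test_consensus_control_predicted(self, consensus_candidate):
        rep = classify_candidate(consensus_candidate)
        assert rep.predicted and rep.core_motif_present and rep.n_passing == 5

    def test_shuffled_consensus_not_predicted(self, consensus_candidate):
        rng = np.random.default_rng(1)
        shuffled = "".join(rng.permutation(list(consensus_candidate.residues)))
        rep = classify_candidate(Sequence(id="shuf", residues=shuffled))
        assert not rep.predicted

    def test_core_motif_ablation_vetoes_prediction(self, consensus_candidate):
        chars = list(consensus_candidate.residues)
        for pos in (92, 94, 96):  # destroy C/S-X-P-X-R
            chars[pos - 1] = "W"
        rep = classify_candidate(Sequence(id="ablated", residues="".join(chars)))
        assert not rep.core_motif_present
        assert not rep.predicted

    def test_prediction_stable_under_flanking_sequence(self, motifs):
        rng = np.random.default_rng(4)
        core = build_consensus_candidate(motifs)
        flank = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 60))
        extended = Sequence(id="ext", residues=flank + core.residues + flank)
        assert classify_candidate(extended).predicted

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_random_sequences_rarely_pass_any_motif(self, seed):
        rng = np.random.default_rng(seed)
        cand = random_protein(rng, 500)
        rep = classify_candidate(cand)
        assert not rep.predicted
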