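import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from cxmotifs import (
    AlignmentParams,
    ProteinRecord,
    align_global,
    assess_conservation,
    map_position,
    pick_ortholog,
    project_topology,
    scan_protein,
)
from cxmotifs.conservation import AlignmentError

from conftest import protein_for, random_sequence
from oracles import rescore_alignment

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def reference_aligner(open_=10, ext=1):
    aligner = PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -open_
    aligner.extend_gap_score = -ext
    aligner.mode = "global"
    return aligner


class TestAligner:
    def test_self_alignment_has_no_gaps_and_diagonal_score(self):
        seq = "EINKLLSRLWVTVYKLAG"
        alignment = align_global(seq, seq)
        assert "-" not in alignment.aligned_query
        assert alignment.score == sum(BLOSUM62[c, c] for c in seq)

    def test_score_matches_dp_oracle(self):
        alignment = align_global("EINKLL", "EINKLL")
        assert alignment.score == reference_aligner().score("EINKLL", "EINKLL")

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_global("A", "")

    def test_unknown_residue_named(self):
        with pytest.raises(AlignmentError, match="O"):
            align_global("AOA", "AAA")

    def test_random_pairs_match_oracle_and_are_symmetric(self, rng):
        aligner = reference_aligner()
        for _ in range(40):
            a = random_sequence(rng, int(rng.integers(3, 60)))
            b = random_sequence(rng, int(rng.integers(3, 60)))
            mine = align_global(a, b)
            assert mine.score == aligner.score(a, b)
            assert align_global(b, a).score == mine.score
            # gap-stripped alignment reproduces the inputs
            assert mine.aligned_query.replace("-", "") == a
            assert mine.aligned_subject.replace("-", "") == b
            # the emitted alignment really achieves the reported score
            assert rescore_alignment(
                mine.aligned_query, mine.aligned_subject, BLOSUM62, 10, 1
            ) == mine.score

    def test_gap_parameters_respected(self, rng):
        params = AlignmentParams(gap_open=5, gap_extend=2)
        aligner = reference_aligner(5, 2)
        for _ in range(15):
            a = random_sequence(rng, int(rng.integers(5, 40)))
            b = random_sequence(rng, int(rng.integers(5, 40)))
            assert align_global(a, b, params).score == aligner.score(a, b)


class TestMapPosition:
    def test_identity(self):
        alignment = align_global("EINKLL" * 42, "EINKLL" * 42)
        assert map_position(alignment, 247) == 247

    def test_gap_marker_and_monotonicity(self, rng):
        a = random_sequence(rng, 50)
        b = a[:20] + a[30:]  # internal deletion in the subject
        alignment = align_global(a, b)
        mapped = [map_position(alignment, q) for q in range(1, 51)]
        assert any(m is None for m in mapped)
        non_gap = [m for m in mapped if m is not None]
        assert non_gap == sorted(non_gap) and len(set(non_gap)) == len(non_gap)

    def test_out_of_range(self):
        alignment = align_global("EINKLL", "EINKLL")
        with pytest.raises(IndexError):
            map_position(alignment, 7)


class TestProjectTopology:
    def test_identity_projection_preserves_boundaries(self, simple_topology):
        seq = random_sequence(np.random.default_rng(1), simple_topology.length)
        alignment = align_global(seq, seq)
        projected = project_topology(alignment, simple_topology, "P2")
        assert [(s.kind, s.start, s.end) for s in projected.segments] == [
            (s.kind, s.start, s.end) for s in simple_topology.segments
        ]

    def test_deletion_shrinks_containing_segment(self, simple_topology):
        rng = np.random.default_rng(2)
        seq = random_sequence(rng, simple_topology.length)
        # delete 5 residues from the middle of the IL (positions 105-109)
        subject = seq[:104] + seq[109:]
        alignment = align_global(seq, subject)
        projected = project_topology(alignment, simple_topology, "P2")
        assert projected.length == len(subject)
        il = projected.segment("IL")
        assert len(il) == len(simple_topology.segment("IL")) - 5
        # flanking TM boundaries stay aligned
        assert projected.segment("TM2").end == simple_topology.segment("TM2").end


class TestPickOrtholog:
    def test_single_candidate(self):
        human = ProteinRecord(id="H", sequence="EINKLLSRLWVTV")
        only = ProteinRecord(id="R", sequence="EINKLLSRLWVAV")
        assert pick_ortholog(human, [only]) is only

    def test_identity_beats_shuffle_and_divergence(self, rng):
        seq = random_sequence(rng, 80)
        human = ProteinRecord(id="H", sequence=seq)
        shuffled = "".join(rng.permutation(list(seq)))
        mutant = list(seq)
        for pos in rng.choice(80, size=4, replace=False):  # 95% identity
            mutant[pos] = "A" if mutant[pos] != "A" else "G"
        far = list(seq)
        for pos in rng.choice(80, size=32, replace=False):  # 60% identity
            far[pos] = "A" if far[pos] != "A" else "G"
        candidates = [
            ProteinRecord(id="SHUF", sequence=shuffled),
            ProteinRecord(id="NEAR", sequence="".join(mutant)),
            ProteinRecord(id="FAR", sequence="".join(far)),
            ProteinRecord(id="SAME", sequence=seq),
        ]
        assert pick_ortholog(human, candidates).id == "SAME"
        assert pick_ortholog(human, candidates[:3]).id == "NEAR"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            pick_ortholog(ProteinRecord(id="H", sequence="MKT"), [])


class TestAssessConservation:
    def _scanned_hit(self, topology, sequence):
        record = protein_for(topology, sequence)
        result = scan_protein(record, topology)
        assert result.hits, "fixture must yield a filtered hit"
        return record, result.hits[0]

    def test_identical_ortholog_conserved_same_anchor(self, simple_topology):
        seq = ["A"] * simple_topology.length
        seq[214:218] = "YVFF"
        seq = "".join(seq)
        human, hit = self._scanned_hit(simple_topology, seq)
        rat = ProteinRecord(id="RAT", sequence=seq)
        call = assess_conservation(hit, human, rat, human_topology=simple_topology)
        assert call.conserved and call.ortholog_anchor == hit.start

    def test_destroyed_anchor_not_conserved(self, simple_topology):
        seq = ["A"] * simple_topology.length
        seq[214:218] = "YVFF"
        human, hit = self._scanned_hit(simple_topology, "".join(seq))
        seq[214] = "G"  # essential tyrosine destroyed
        rat = ProteinRecord(id="RAT", sequence="".join(seq))
        call = assess_conservation(hit, human, rat, human_topology=simple_topology)
        assert not call.conserved and call.ortholog_anchor is None

    def test_shifted_motif_found_within_spacer_slack(self, simple_topology):
        seq = ["A"] * simple_topology.length
        seq[214:218] = "YVFF"
        human, hit = self._scanned_hit(simple_topology, "".join(seq))
        shifted = list(seq)
        shifted[214:218] = "AAAA"
        shifted[212:216] = "YVFF"  # anchor two residues upstream
        rat = ProteinRecord(id="RAT", sequence="".join(shifted))
        call = assess_conservation(hit, human, rat, human_topology=simple_topology)
        assert call.conserved and call.ortholog_anchor == 213

    def test_same_family_match_in_other_domain_does_not_count(self, simple_topology):
        seq = ["A"] * simple_topology.length
        seq[214:218] = "YVFF"
        human, hit = self._scanned_hit(simple_topology, "".join(seq))
        moved = ["A"] * simple_topology.length
        moved[100:104] = "YVFF"  # IL of the ortholog, far outside the window
        rat = ProteinRecord(id="RAT", sequence="".join(moved))
        call = assess_conservation(hit, human, rat, human_topology=simple_topology)
        assert not call.conserved

    def test_domain_level_mode_is_lenient(self, simple_topology):
        seq = ["A"] * simple_topology.length
        seq[214:218] = "YVFF"
        human, hit = self._scanned_hit(simple_topology, "".join(seq))
        moved = ["A"] * simple_topology.length
        moved[224:228] = "YVFF"  # still CT, but outside the aligned window
        rat = ProteinRecord(id="RAT", sequence="".join(moved))
        strict = assess_conservation(hit, human, rat, human_topology=simple_topology)
        lenient = assess_conservation(
            hit, human, rat, human_topology=simple_topology, mode="domain_level"
        )
        assert not strict.conserved and lenient.conserved

    def test_synonymous_changes_outside_footprint_ignored(self, simple_topology):
        rng = np.random.default_rng(3)
        seq = list(random_sequence(rng, simple_topology.length))
        seq[214:218] = "YVFF"
        human = protein_for(simple_topology, "".join(seq))
        result = scan_protein(human, simple_topology)
        hit = next(h for h in result.hits if h.start == 215)
        mutated = list(seq)
        for pos in (5, 50, 100, 160, 225):
            mutated[pos] = "G" if mutated[pos] != "G" else "H"
        rat = ProteinRecord(id="RAT", sequence="".join(mutated))
        call = assess_conservation(hit, human, rat, human_topology=simple_topology)
        assert call.conserved
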