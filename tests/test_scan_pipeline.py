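import pytest

from cxmotifs import (
    DEFAULT_SCAN,
    ProteinRecord,
    ScanConfig,
    enumerate_hits,
    filter_hits,
    scan_junction,
    scan_protein,
    summarize,
)
from cxmotifs.scan_pipeline import categorize, tm_distance_of
from cxmotifs.synthetic_data import PlantedMotif, SyntheticSpec, generate

from conftest import protein_for


def build_sequence(topology, inserts: dict[int, str]) -> str:
    """An all-alanine sequence with peptides overwritten at 1-based anchors."""
    seq = ["A"] * topology.length
    for start, peptide in inserts.items():
        seq[start - 1:start - 1 + len(peptide)] = peptide
    return "".join(seq)


# simple_topology segments: NT 1-20, TM1 21-40, E1 41-70, TM2 71-90,
# IL 91-130, TM3 131-150, E2 151-180, TM4 181-200, CT 201-230


class TestFilter:
    def test_domain_and_distance_rules(self, simple_topology):
        seq = build_sequence(simple_topology, {
            215: "YVFF",     # CT, 14 residues past TM4 -> kept
            206: "YKLV",     # CT, 5 residues past TM4 -> too close
            160: "EINKLL",   # E2 -> not a searched domain
            101: "EINKLL",   # IL, 10 from TM2 and 24 from TM3 -> kept
        })
        hits = enumerate_hits(seq, protein_id="P1")
        kept = filter_hits(hits, simple_topology)
        spans = {(h.start, h.domain_kind, h.tm_distance) for h in kept}
        assert spans == {(215, "CT", 14), (101, "IL", 10)}

    def test_whitelist_exempts_distance_rule(self, simple_topology):
        seq = build_sequence(simple_topology, {206: "YKLV"})
        hits = enumerate_hits(seq, protein_id="P1")
        config = ScanConfig(whitelist={("P1", 206, "tyrosine")})
        kept = filter_hits(hits, simple_topology, config)
        assert [(h.start, h.whitelisted, h.tm_distance) for h in kept] == [(206, True, 5)]
        # the whitelist is specific: a different anchor stays excluded
        assert filter_hits(hits, simple_topology, ScanConfig(
            whitelist={("P1", 207, "tyrosine")})) == []

    def test_boundary_spanning_hit_dropped(self, simple_topology):
        seq = build_sequence(simple_topology, {199: "YVFF"})  # spans TM4|CT
        hits = enumerate_hits(seq, protein_id="P1")
        assert any(h.start == 199 for h in hits)
        assert filter_hits(hits, simple_topology) == []

    def test_il_distance_is_min_of_both_flanks(self, simple_topology):
        # anchor 124, end 129: 33 from TM2 but only 1 from TM3
        seq = build_sequence(simple_topology, {124: "EINKLL"})
        hits = [h for h in enumerate_hits(seq, protein_id="P1") if h.start == 124]
        assert tm_distance_of(hits[0], simple_topology, "IL") == 1
        assert filter_hits(hits, simple_topology) == []

    def test_monotone_in_min_tm_distance(self):
        spec = SyntheticSpec(seed=7, n_proteins=5, planted=(
            PlantedMotif("tyrosine", "canonical", "CT", 12),
            PlantedMotif("dileucine", "canonical", "IL", 8),
        ))
        records, topologies, _ = generate(spec)
        for record in records:
            hits = enumerate_hits(record.sequence, protein_id=record.id)
            counts = [
                len(filter_hits(hits, topologies[record.id],
                                ScanConfig(min_tm_distance=d, whitelist=frozenset())))
                for d in (0, 3, 6, 10, 15, 25)
            ]
            assert counts == sorted(counts, reverse=True)


class TestJunction:
    def test_canonical_terminus_at_boundary(self, simple_topology):
        seq = build_sequence(simple_topology, {198: "EVVYLI"})
        jm = scan_junction(protein_for(simple_topology, seq), simple_topology)
        assert jm.start == 198
        assert (jm.first_slot, jm.terminus, jm.terminus_class) == ("E", "LI", "canonical")

    @pytest.mark.parametrize("terminus,cls", [
        ("LG", "last_atypical"),
        ("AL", "second_last_atypical"),
        ("AG", "both_atypical"),
    ])
    def test_terminus_classes(self, simple_topology, terminus, cls):
        seq = build_sequence(simple_topology, {198: "EVVY" + terminus})
        jm = scan_junction(protein_for(simple_topology, seq), simple_topology)
        assert jm.terminus_class == cls

    def test_closest_anchor_wins_upstream_on_tie(self, simple_topology):
        # anchors at 198 and 202 are both 2 residues from the TM4 end (200)
        seq = build_sequence(simple_topology, {198: "E", 202: "E"})
        jm = scan_junction(protein_for(simple_topology, seq), simple_topology)
        assert jm.start == 198
        # an anchor strictly closer to the TM4 end beats both
        seq = build_sequence(simple_topology, {198: "E", 199: "D", 202: "E"})
        jm = scan_junction(protein_for(simple_topology, seq), simple_topology)
        assert (jm.start, jm.first_slot) == (199, "D")

    def test_absent_without_acidic_anchor(self, simple_topology):
        seq = build_sequence(simple_topology, {})
        assert scan_junction(protein_for(simple_topology, seq), simple_topology) is None


class TestCategorize:
    def test_priority_order(self, simple_topology):
        cases = {
            "YVFF": "TYR_CANONICAL",        # canonical tyrosine wins
            "EINKLL": "DILEU_CANONICAL",
            "LKDILR": "NONCANONICAL_ONLY",
        }
        for peptide, category in cases.items():
            seq = build_sequence(simple_topology, {215: peptide})
            record = protein_for(simple_topology, seq)
            assert scan_protein(record, simple_topology).category == category
        seq = build_sequence(simple_topology, {})
        assert scan_protein(protein_for(simple_topology, seq),
                            simple_topology).category == "NONE"

    def test_canonical_tyrosine_outranks_canonical_dileucine(self, simple_topology):
        seq = build_sequence(simple_topology, {211: "EINKLL", 221: "YVFF"})
        record = protein_for(simple_topology, seq)
        assert scan_protein(record, simple_topology).category == "TYR_CANONICAL"


class TestSummarize:
    def test_empty_input_all_zero(self):
        counts = summarize([])
        assert counts.n_proteins == 0
        assert counts.n_motifs_total == 0
        assert all(v == 0 for v in counts.category_counts.values())

    def test_counts_partition_proteins(self, simple_topology):
        seqs = {
            "P_tyr": {215: "YVFF"},
            "P_dileu": {215: "EINKLL"},
            "P_none": {},
        }
        from cxmotifs import make_topology
        lengths = {s.kind: len(s) for s in simple_topology.segments}
        results = []
        for pid, inserts in seqs.items():
            topo = make_topology(pid, lengths)
            seq = build_sequence(topo, inserts)
            results.append(scan_protein(ProteinRecord(id=pid, sequence=seq), topo))
        counts = summarize(results)
        assert sum(counts.category_counts.values()) == counts.n_proteins == 3
        assert counts.category_counts["TYR_CANONICAL"] == 1
        assert counts.category_counts["DILEU_CANONICAL"] == 1
        assert counts.category_counts["NONE"] == 1
        assert counts.n_canonical_any == 2
        assert counts.location_counts.get("CT_only", 0) == 2

    def test_duplicate_protein_rejected(self, simple_topology):
        seq = build_sequence(simple_topology, {})
        result = scan_protein(protein_for(simple_topology, seq), simple_topology)
        with pytest.raises(ValueError, match="duplicate"):
            summarize([result, result])
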