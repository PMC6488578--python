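import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nescan import consensus as cns
from nescan.io_formats import EvidenceAnnotation

from _oracle import oracle_groups, oracle_scan

AA = list("ACDEFGHIKLMNPQRSTVWY")


def match_set(seq):
    return {(m.class_id, m.direction, m.phi_positions, m.ta_used)
            for m in cns.scan(seq)}


class TestCompilePatterns:
    def test_default_class_set_has_nine_specs(self):
        specs = cns.compile_patterns()
        assert len(specs) == 9
        assert {s.class_id for s in specs} == set(cns.CLASS_ORDER)

    def test_class4_pro_requirement_spans_final_spacer(self):
        (c4,) = [s for s in cns.compile_patterns() if s.class_id == "4"]
        assert c4.pro_requirement == (8, 10)
        assert c4.phi_offsets == (0, 4, 7, 11)

    def test_reverse_classes_carry_bulky_rule(self):
        for s in cns.compile_patterns():
            assert s.reverse_bulky_rule == s.class_id.endswith("-R")
            assert s.direction == ("reverse" if s.class_id.endswith("-R")
                                   else "forward")

    def test_unknown_class_rejected(self):
        with pytest.raises(cns.PatternError):
            cns.compile_patterns(["5x"])


class TestScanWorkedExamples:
    """In-sequence worked examples with registries checked by hand."""

    @pytest.mark.parametrize("seq,cid,local_phis", [
        ("STVDEMTKKFGTLTIHD", "1a", (6, 10, 13, 15)),    # MVM NS2
        ("VDLACTPTDVRDVDI", "1a", (6, 10, 13, 15)),      # Cyclin D1, Thr at Φ1
        ("ILKTLSEVEESISTL", "3", (5, 8, 12, 15)),        # COMMD1
        ("SSLQELVQQFEALPGDLV", "4", (6, 10, 13, 17)),    # X11L2
    ])
    def test_forward_registries(self, seq, cid, local_phis):
        assert any(m.class_id == cid and m.phi_positions == local_phis
                   for m in cns.scan(seq))

    def test_cyclin_d1_uses_thr_substitution(self):
        (m,) = [m for m in cns.scan("VDLACTPTDVRDVDI") if m.class_id == "1a"]
        assert m.ta_used

    def test_reverse_class_match_registry(self):
        # CPEB4: the mirrored class-1a registry runs C→N in the sequence
        matches = [m for m in cns.scan("RTFDMHSLESSLIDIMR")
                   if m.class_id == "1a-R"]
        assert any(m.phi_positions == (12, 8, 5, 3) for m in matches)

    def test_no_match_without_hydrophobics(self):
        assert cns.scan("A" * 16) == []

    def test_unknown_residue_never_satisfies_phi_or_nopw(self):
        base = "SSLESSLSSLSLSS"   # class-1a registry at 3,7,10,12
        assert any(m.class_id == "1a" for m in cns.scan(base))
        x_at_phi = base[:2] + "X" + base[3:]
        assert not any(m.class_id == "1a" for m in cns.scan(x_at_phi))
        x_in_nopw = base[:7] + "X" + base[8:]
        assert not any(m.class_id == "1a" for m in cns.scan(x_in_nopw))


class TestScannerOracleEquivalence:
    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        alphabet = AA + ["X"]
        for _ in range(25):
            seq = "".join(rng.choice(alphabet, 200))
            assert match_set(seq) == oracle_scan(seq)

    def test_reverse_equals_mirrored_forward_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(AA, 150))
            L = len(seq)
            rev_hits = {(m.class_id, m.phi_positions)
                        for m in cns.scan(seq) if m.direction == "reverse"}
            specs = cns.compile_patterns(["1a", "1c"])
            mirrored = set()
            for m in cns.scan(seq[::-1], specs):
                p3, p4 = m.phi_positions[2], m.phi_positions[3]
                if not ({seq[::-1][p3 - 1], seq[::-1][p4 - 1]} & set("LFM")):
                    continue
                if m.ta_used:
                    continue
                mirrored.add((m.class_id + "-R",
                              tuple(L - p + 1 for p in m.phi_positions)))
            assert rev_hits == mirrored


class TestPhi0:
    def test_super_pki_phi0_is_hydrophobic(self):
        seq = "NLNELALKLAGLDINK"
        (m,) = [m for m in cns.scan(seq) if m.class_id == "1a"]
        cns.detect_phi0(m, seq)
        assert (m.phi0, m.phi0_hydrophobic) == (2, True)

    def test_pki_phi0_is_serine(self):
        seq = "NSNELALKLAGLDINK"
        (m,) = [m for m in cns.scan(seq) if m.class_id == "1a"]
        cns.detect_phi0(m, seq)
        assert (m.phi0, m.phi0_hydrophobic) == (2, False)

    def test_phi0_unassigned_when_before_sequence_start(self):
        seq = "LESSLSELSIS" + "G" * 5   # Φ1 at position 1
        m = [m for m in cns.scan(seq) if m.class_id == "1a"
             and m.phi_positions[0] == 1][0]
        cns.detect_phi0(m, seq)
        assert m.phi0 is None

    def test_class3_has_no_phi0_slot(self):
        seq = "SSVSSILKTLSEVEESISTLSS"
        m = [m for m in cns.scan(seq) if m.class_id == "3"][0]
        cns.detect_phi0(m, seq)
        assert m.phi0 is None


class TestPriority:
    @pytest.mark.parametrize("cid,ta,phi0h,want", [
        ("1a", False, True, 1),
        ("1a", False, False, 2),
        ("1a-R", False, False, 2), ("2", False, False, 2),
        ("3", False, False, 2), ("4", False, False, 2),
        ("1c", False, False, 2),
        ("1a", True, False, 3), ("1c", True, False, 3),
        ("1b", False, False, 4), ("1d", False, False, 4),
        ("1c-R", False, False, 4), ("2", True, False, 4), ("3", True, False, 4),
        ("1b", True, False, 5), ("1d", True, False, 5),
    ])
    def test_priority_table(self, cid, ta, phi0h, want):
        m = cns.ConsensusMatch("p", cid, "forward", (1, 5, 8, 10), ta,
                               phi0_hydrophobic=phi0h)
        assert cns.assign_priority(m) == want

    def test_priority_total_over_scanned_matches(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(AA, 250))
            for m in cns.scan_sequence(seq):
                assert m.priority in (1, 2, 3, 4, 5)


class TestExtractWindow:
    def _match(self, phi1, phi0=None, direction="forward"):
        phis = (phi1, phi1 + 4, phi1 + 7, phi1 + 9)
        m = cns.ConsensusMatch("p", "1a", direction, phis, False)
        m.phi0 = phi0
        return m

    def test_window_spans_phi0_minus_one_to_phi4_plus_two(self):
        m = self._match(82, phi0=79)
        cns.extract_window(m, "A" * 200)
        assert (m.seg_start, m.seg_end) == (78, 93)

    def test_window_clamped_at_c_terminus(self):
        m = self._match(82, phi0=79)
        cns.extract_window(m, "A" * 92)
        assert m.seg_end == 92

    def test_window_clamped_at_n_terminus(self):
        m = self._match(1)
        cns.extract_window(m, "A" * 50)
        assert m.seg_start == 1

    def test_no_window_exceeds_25_residues(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = "".join(rng.choice(AA, 300))
            for m in cns.scan_sequence(seq):
                assert m.seg_end - m.seg_start + 1 <= 25


class TestGroupOverlaps:
    def _matches(self, starts):
        out = []
        for s in starts:
            m = cns.ConsensusMatch("p", "1a", "forward",
                                   (s + 4, s + 8, s + 11, s + 13), False)
            m.seg_start, m.seg_end, m.priority = s, s + 15, 2
            out.append(m)
        return out

    def test_chained_starts_form_one_group(self):
        groups = cns.group_overlaps(self._matches([10, 12, 14]))
        assert len(groups) == 1

    def test_gap_of_delta_splits_groups(self):
        groups = cns.group_overlaps(self._matches([10, 16]))
        assert len(groups) == 2

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 120), min_size=1, max_size=25),
           st.integers(2, 9))
    def test_grouping_equals_connected_components(self, starts, delta):
        groups = cns.group_overlaps(self._matches(starts), delta)
        got = sorted((sorted(m.seg_start for m in g) for g in groups),
                     key=lambda g: g[0])
        assert got == oracle_groups(starts, delta)


class TestLabelCandidate:
    def _match(self, phi2, phi4):
        return cns.ConsensusMatch("p", "1a", "forward",
                                  (phi2 - 4, phi2, phi4 - 2, phi4), False)

    def test_overlap_with_evidence_is_candidate(self):
        lab = cns.label_candidate(
            self._match(83, 91), [EvidenceAnnotation("mutation", 77, 93)])
        assert lab.label == "cand" and len(lab.matched_evidence) == 1

    def test_disjoint_evidence_is_false_positive(self):
        lab = cns.label_candidate(
            self._match(10, 18), [EvidenceAnnotation("functional", 30, 45)])
        assert lab.label == "fp" and not lab.matched_evidence

    def test_single_residue_evidence_at_phi3_counts(self):
        m = self._match(83, 91)
        phi3 = m.phi_positions[2]
        lab = cns.label_candidate(m, [EvidenceAnnotation("site", phi3, phi3)])
        assert lab.label == "cand"


class TestTable1Registries:
    """The packaged benchmark table doubles as a scanner ground-truth set."""

    def test_scanner_recovers_all_annotated_registries(self, table1):
        for entry in table1:
            if not entry.expect_scan:
                continue
            want = tuple(sorted(entry.phi_local))
            found = [m for m in cns.scan_sequence(entry.sequence)
                     if m.class_id == entry.nes_class and m.registry == want]
            assert found, f"{entry.name}: {entry.nes_class} {want} not found"

    def test_non_fitting_entries_have_no_annotated_registry_match(self, table1):
        for entry in table1:
            if entry.consensus_fit or entry.nes_class is None:
                continue
            want = tuple(sorted(entry.phi_local))
            found = [m for m in cns.scan_sequence(entry.sequence)
                     if m.class_id == entry.nes_class and m.registry == want]
            assert not found, f"{entry.name} should not fit {entry.nes_class}"
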