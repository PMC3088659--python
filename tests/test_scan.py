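"""Scanner behaviour: folding, core matching, scoring, end-to-end recovery."""

import pytest

from hhscan import (
    AlphabetError,
    ScanConfig,
    Topology,
    fold_stem,
    generate_hammerhead,
    match_core,
    reverse_complement,
    scan,
    score_hit,
)
from hhscan.synthetic import hit_from_truth


class TestFoldStem:
    def test_perfect_antiparallel_complement(self):
        stem = fold_stem("GCGC", "GCGC")
        assert stem is not None
        assert stem.n_bp == 4
        assert stem.n_mispairs == 0 and stem.n_bulges == 0

    def test_innermost_wobble_counts_as_paired(self):
        # 5' half starts with G, 3' half ends with U: a G-U closing pair
        stem = fold_stem("GAGC", "GCUU")
        assert stem is not None
        assert stem.n_wobble >= 1
        assert stem.innermost_paired

    def test_two_bp_stem_accepted_at_min_two(self):
        stem = fold_stem("GC", "GC", limits={"min_bp": 2})
        assert stem is not None and stem.n_bp == 2

    def test_below_minimum_returns_none(self):
        assert fold_stem("AA", "GG", limits={"min_bp": 2}) is None

    def test_wobble_flag_respected(self):
        assert fold_stem("GG", "UU", allow_wobble=False, limits={"min_bp": 2}) is None
        assert fold_stem("GG", "UU", allow_wobble=True, limits={"min_bp": 2}).n_bp == 2


class TestMatchCore:
    def _placement(self, seq_parts):
        """Lay box1 + box2 + closing pair + 17 head-to-tail for testing."""
        seq = "".join(seq_parts)
        labels = ["3", "4", "5", "6", "7", "8", "9",
                  "12", "13", "14", "15.1", "16.1", "17"]
        return seq, {lbl: i for i, lbl in enumerate(labels)}

    def test_consensus_with_any_n7_and_h17(self):
        seq, placement = self._placement(["CUGAUGA", "GAA", "A", "U", "C"])
        ok, devs = match_core(seq, placement)
        assert ok and devs == {}

    def test_g_at_17_is_excluded_by_h(self):
        seq, placement = self._placement(["CUGAUGA", "GAA", "A", "U", "G"])
        ok, devs = match_core(seq, placement)
        assert not ok and devs == {"17": "G"}

    def test_fixed_letter_violation_reported(self):
        seq, placement = self._placement(["CUGAUGG", "GAA", "A", "U", "C"])
        ok, devs = match_core(seq, placement)
        assert not ok and devs == {"9": "G"}

    def test_out_of_order_placement_rejected(self):
        seq, placement = self._placement(["CUGAUGA", "GAA", "A", "U", "C"])
        placement["4"], placement["5"] = placement["5"], placement["4"]
        with pytest.raises(ValueError, match="out of order"):
            match_core(seq, placement)


class TestScoring:
    @pytest.fixture
    def clean_hit(self):
        seq, truth = generate_hammerhead("III", (6, 3, 5), (6, 6, 6), seed=5)
        return hit_from_truth(seq, truth)

    def test_score_is_total_bp_minus_defects(self, clean_hit):
        assert score_hit(clean_hit) == 14.0  # 6 + 3 + 5, no defects, no pk

    def test_pseudoknot_adds_twice_its_length(self, clean_hit):
        from hhscan.model import Pseudoknot
        clean_hit.pseudoknot = Pseudoknot((0, 4), (10, 14), 4, 0, "loopI-3'tail")
        assert score_hit(clean_hit) == 14.0 + 8.0

    def test_single_extra_mispair_changes_score_by_one(self, clean_hit):
        before = score_hit(clean_hit)
        clean_hit.stems["I"].n_mispairs += 1
        assert before - score_hit(clean_hit) == 1.0


class TestScanEndToEnd:
    def test_planted_type_iii_recovered_exactly(self, config, rng):
        seq, truth = generate_hammerhead("III", (6, 4, 6), (6, 6, 6), pk_len=6, seed=101)
        bg5 = "".join("ACGU"[int(rng.integers(0, 4))] for _ in range(220))
        bg3 = "".join("ACGU"[int(rng.integers(0, 4))] for _ in range(500 - 220 - len(seq)))
        record = bg5 + seq + bg3
        hits = scan(record, config, record_id="r")
        strict = [h for h in hits if h.verdict.status == "pass-strict"]
        assert len(strict) == 1
        hit = strict[0]
        off = len(bg5)
        assert hit.interval == (truth["interval"][0] + off, truth["interval"][1] + off)
        assert hit.cleavage_site == truth["cleavage_site"] + off
        assert hit.topology is Topology.III
        assert hit.pseudoknot is not None and hit.pseudoknot.n_bp == 6

    def test_minus_strand_symmetry(self, config):
        seq, truth = generate_hammerhead("II", (5, 3, 5), (7, 6, 5), seed=77)
        L = len(seq)
        hits = scan(reverse_complement(seq), config, record_id="rc")
        strict = [h for h in hits if h.verdict.status == "pass-strict"]
        assert len(strict) == 1
        hit = strict[0]
        assert hit.strand == "-"
        assert hit.interval == (L - truth["interval"][1], L - truth["interval"][0])
        assert hit.cleavage_site == L - truth["cleavage_site"]

    def test_empty_and_subminimal_sequences(self, config):
        assert scan("", config) == []
        assert scan("ACGUACGU", config) == []

    def test_illegal_character_names_record_and_offset(self, config):
        with pytest.raises(AlphabetError, match=r"badrec.*offset 2"):
            scan("AC1GU", config, record_id="badrec")

    def test_score_invariant_to_outside_context(self, config):
        seq, _ = generate_hammerhead("I", (5, 4, 5), (6, 6, 6), seed=13)
        h1 = scan("A" * 40 + seq + "C" * 40, config)
        h2 = scan("G" * 15 + seq + "U" * 25, config)
        s1 = [h for h in h1 if h.verdict.status == "pass-strict"]
        s2 = [h for h in h2 if h.verdict.status == "pass-strict"]
        assert s1 and s2
        assert s1[0].score == s2[0].score

    def test_no_hit_exceeds_window_span(self, config):
        seq, _ = generate_hammerhead("II", (8, 4, 8), (8, 8, 8), pk_len=5, seed=3)
        for h in scan(seq, config):
            assert h.end - h.start <= config.max_span


class TestScanConfig:
    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(stem_bp={"I": (5, 2), "II": (1, 10), "III": (2, 12)})
        with pytest.raises(ValueError):
            ScanConfig(mode="lenient")
        with pytest.raises(ValueError):
            ScanConfig(max_span=10)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("stem_II_min_bp: 2\nmax_span: 150\nmode: variant\n")
        cfg = ScanConfig.from_yaml(p)
        assert cfg.stem_bp["II"] == (2, 10)
        assert cfg.max_span == 150 and cfg.mode == "variant"

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("stemx: 2\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            ScanConfig.from_yaml(p)
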