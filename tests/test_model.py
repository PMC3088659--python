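"""Domain-model invariants: alphabet, pairing, consensus, topology layouts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhscan.model import (
    CORE_LABELS,
    CYCLE,
    AlphabetError,
    CoreConsensus,
    KineticsTrace,
    NucSet,
    Topology,
    complement,
    is_pair,
    normalize_sequence,
    reverse_complement,
    topology_layout,
)


class TestPairing:
    @pytest.mark.parametrize(
        "x, y, wobble, expected",
        [
            ("G", "C", True, True),
            ("G", "C", False, True),
            ("A", "U", False, True),
            ("G", "U", True, True),   # wobble pairs count as paired
            ("U", "G", True, True),
            ("G", "U", False, False),
            ("A", "C", True, False),
            ("A", "A", True, False),
        ],
    )
    def test_pair_table(self, x, y, wobble, expected):
        assert is_pair(x, y, allow_wobble=wobble) is expected

    def test_ambiguity_codes_never_pair(self):
        assert not is_pair("N", "N")
        assert not is_pair("R", "Y")

    def test_non_nucleotide_raises(self):
        with pytest.raises(AlphabetError):
            is_pair("X", "A")
        with pytest.raises(AlphabetError):
            complement("Z")

    @given(st.sampled_from("ACGU"))
    @settings(derandomize=True)
    def test_complement_is_involution(self, base):
        assert complement(complement(base)) == base
        assert is_pair(base, complement(base), allow_wobble=False)

    def test_reverse_complement_handles_iupac(self):
        assert reverse_complement("GAUC") == "GAUC"
        assert reverse_complement("NRY") == "RYN"


class TestAlphabet:
    def test_normalize_uppercases_and_converts_t(self):
        assert normalize_sequence("gattaca") == "GAUUACA"

    def test_normalize_error_names_record_and_offset(self):
        with pytest.raises(AlphabetError, match=r"rec7.*offset 3"):
            normalize_sequence("ACG!ACG", "rec7")

    def test_nucset_subset_rule(self):
        n = NucSet.from_symbol("N")
        h = NucSet.from_symbol("H")
        assert n.matches("A") and n.matches("N") and n.matches("R")
        assert h.matches("C") and h.matches("Y")
        assert not h.matches("G") and not h.matches("N")
        # a masked (N) input letter never satisfies a fixed consensus letter
        assert not NucSet.from_symbol("C").matches("N")

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            NucSet("X", frozenset())


class TestCoreConsensus:
    def test_default_has_thirteen_positions(self):
        cc = CoreConsensus.default()
        assert set(cc.positions) == set(CORE_LABELS)
        assert len(CORE_LABELS) == 13
        assert cc.allowed("7").allowed == frozenset("ACGU")   # N7: any nucleotide
        assert cc.allowed("17").allowed == frozenset("ACU")   # H17: not G
        assert cc.allowed("15.1").symbol == "A"
        assert cc.allowed("16.1").symbol == "U"

    def test_missing_position_rejected(self):
        cc = CoreConsensus.default()
        broken = dict(cc.positions)
        del broken["5"]
        with pytest.raises(ValueError):
            CoreConsensus(broken)


class TestTopologyLayout:
    def test_type_ii_order_matches_architecture(self):
        # stems I and III closed by hairpin loops, stem II open at the termini
        assert topology_layout(Topology.II) == [
            "stem2_b", "box2", "stem3_a", "loop3", "stem3_b", "res17",
            "stem1_a", "loop1", "stem1_b", "box1", "stem2_a",
        ]

    @pytest.mark.parametrize("topo", list(Topology))
    def test_each_layout_is_a_valid_permutation(self, topo):
        layout = topology_layout(topo)
        assert layout.count("box1") == 1
        assert layout.count("box2") == 1
        # exactly two terminal loops; the open stem has none
        loops = [e for e in layout if e.startswith("loop")]
        assert len(loops) == 2
        open_num = {"I": "1", "II": "2", "III": "3"}[topo.open_stem]
        assert f"loop{open_num}" not in layout
        # the open stem's halves sit at the termini
        assert layout[0] == f"stem{open_num}_b"
        assert layout[-1] == f"stem{open_num}_a"

    def test_layouts_are_distinct_and_cyclically_consistent(self):
        layouts = {topo: tuple(topology_layout(topo)) for topo in Topology}
        assert len(set(layouts.values())) == 3  # bijection
        # re-closing the circle recovers the canonical cyclic order
        cycle2 = CYCLE + CYCLE
        for topo, layout in layouts.items():
            s = " ".join(cycle2)
            assert " ".join(layout) in s

    def test_type_iii_cleavage_near_five_prime(self):
        layout = topology_layout(Topology.III)
        assert layout.index("res17") == 1  # right after the 16.x half

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            topology_layout("IV")


class TestKineticsTrace:
    def test_valid_trace(self):
        tr = KineticsTrace([0.0, 1.0, 2.0], [0.0, 0.3, 0.5])
        assert len(tr) == 3

    @pytest.mark.parametrize(
        "times, fracs",
        [
            ([0.0, 1.0], [0.0, 0.1]),             # too few points
            ([0.0, 1.0, 1.0], [0.0, 0.1, 0.2]),   # not strictly increasing
            ([-1.0, 1.0, 2.0], [0.0, 0.1, 0.2]),  # negative time
            ([0.0, 1.0, 2.0], [0.0, 0.5, 1.2]),   # fraction above 1
        ],
    )
    def test_invalid_traces_rejected(self, times, fracs):
        with pytest.raises(ValueError):
            KineticsTrace(times, fracs)
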