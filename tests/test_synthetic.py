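"""Generator guarantees: determinism, consistency with the filters, decoys."""

import collections

import numpy as np
import pytest

from hhscan import (
    apply_strict_filters,
    apply_variant_catalog,
    generate_benchmark,
    generate_decoy,
    generate_hammerhead,
)
from hhscan.filters import DEFAULT_VARIANT_CATALOG
from hhscan.synthetic import (
    GenerationError,
    dinucleotide_shuffle,
    enumerate_core_mutants,
    hit_from_truth,
)


class TestGenerateHammerhead:
    def test_deterministic_per_seed(self):
        a = generate_hammerhead("II", (6, 1, 6), (8, 6, 6), pk_len=6, seed=42)
        b = generate_hammerhead("II", (6, 1, 6), (8, 6, 6), pk_len=6, seed=42)
        assert a[0] == b[0] and a[1] == b[1]

    def test_one_bp_stem_ii_with_six_bp_pseudoknot(self):
        # the architecture of the weakest natural stem II: 1 bp + a 6 bp pk
        seq, truth = generate_hammerhead("II", (6, 1, 6), (8, 6, 6), pk_len=6, seed=42)
        assert len(truth["stems"]["II"]["columns"]) == 1
        assert truth["pseudoknot"]["n_bp"] == 6
        hit = hit_from_truth(seq, truth)
        assert apply_strict_filters(hit).status == "pass-strict"

    def test_sub_threshold_pseudoknot_rejected(self):
        with pytest.raises(GenerationError, match=">= 4"):
            generate_hammerhead("II", (6, 4, 6), (8, 6, 6), pk_len=3, seed=1)

    def test_loop_shorter_than_pseudoknot_rejected(self):
        with pytest.raises(GenerationError, match="shorter"):
            generate_hammerhead("III", (6, 4, 6), (4, 6, 6), pk_len=6, seed=1)

    def test_stem_outside_config_range_rejected(self):
        with pytest.raises(GenerationError, match="stem I"):
            generate_hammerhead("I", (1, 4, 6), (6, 6, 6), seed=1)

    @pytest.mark.parametrize("topo", ["I", "II", "III"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_positive_passes_strict_filters(self, topo, seed):
        seq, truth = generate_hammerhead(topo, (7, 3, 5), (6, 6, 6), seed=seed)
        assert apply_strict_filters(hit_from_truth(seq, truth)).status == "pass-strict"

    @pytest.mark.parametrize("entry", DEFAULT_VARIANT_CATALOG, ids=lambda e: e.name)
    def test_variant_positives_pass_variant_mode(self, entry):
        seq, truth = generate_hammerhead(
            "III", (6, 5, 6), (6, 6, 6), variant=entry.name, seed=3
        )
        hit = hit_from_truth(seq, truth)
        assert apply_strict_filters(hit).status == "rejected"
        assert apply_variant_catalog(hit).status == "pass-variant"
        assert [v.name for v in hit.variants] == [entry.name]


class TestDecoys:
    @pytest.fixture
    def base(self):
        return generate_hammerhead("I", (6, 4, 6), (6, 6, 6), seed=14)

    def test_core_mutant_differs_at_exactly_one_position(self, base):
        seq, truth = generate_decoy(base, "core-mutant", seed=2)
        diffs = [i for i, (x, y) in enumerate(zip(base[0], seq)) if x != y]
        assert len(diffs) == 1
        assert truth["expected_reason"] == "core_mutation"

    def test_adjacent_mispair_is_one_stem_substitution(self, base):
        seq, truth = generate_decoy(base, "adjacent-mispair", seed=2)
        diffs = [i for i, (x, y) in enumerate(zip(base[0], seq)) if x != y]
        assert len(diffs) == 1
        sid = truth["defect"]["stem"]
        cols = truth["stems"][sid]["columns"][0]
        assert diffs[0] in cols

    def test_shuffle_preserves_length_and_dinucleotides(self, base):
        rng = np.random.default_rng(0)
        seq = base[0]
        shuffled, truth = generate_decoy(base, "shuffled", seed=5)
        assert len(shuffled) == len(seq)
        assert truth["negative"] is True

        def dinucs(s):
            return collections.Counter(s[i:i + 2] for i in range(len(s) - 1))

        assert dinucs(shuffled) == dinucs(seq)
        assert shuffled != seq  # astronomically unlikely to be identical

    def test_unknown_kind_rejected(self, base):
        with pytest.raises(GenerationError, match="unknown decoy kind"):
            generate_decoy(base, "scrambled-eggs", seed=0)

    def test_core_mutant_enumeration_is_exhaustive(self):
        mutants = enumerate_core_mutants()
        assert len(mutants) == 34  # 9 fixed letters x3 + closing pair x3x2 + H17 x1
        by_label = collections.Counter(lbl for lbl, _ in mutants)
        assert by_label["7"] == 0   # N7 admits any nucleotide
        assert by_label["17"] == 1  # only G is disallowed at 17
        assert all(by_label[l] == 3 for l in ("3", "4", "5", "6", "8", "9"))


class TestBenchmark:
    def test_counts_and_truth_rows(self):
        records, truth = generate_benchmark(5, 4, bg_len=300, seed=1)
        assert len(records) == 9
        assert len(truth) == 5
        assert set(truth["record"]) == {f"pos_{i:04d}" for i in range(5)}
        for _, row in truth.iterrows():
            assert 0 <= row["start"] < row["end"]
            assert row["start"] < row["cleavage_site"] <= row["end"]

    def test_no_positives_means_empty_truth(self):
        records, truth = generate_benchmark(0, 3, bg_len=300, seed=2)
        assert len(records) == 3 and truth.empty

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_benchmark(-1, 0, seed=0)

    def test_deterministic(self):
        a = generate_benchmark(3, 3, bg_len=300, seed=7)
        b = generate_benchmark(3, 3, bg_len=300, seed=7)
        assert a[0] == b[0]
        assert a[1].equals(b[1])


class TestDinucleotideShuffle:
    def test_composition_preserved_on_random_sequences(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(20, 120))))
            out = dinucleotide_shuffle(seq, rng)
            assert len(out) == len(seq)
            c1 = collections.Counter(seq[i:i + 2] for i in range(len(seq) - 1))
            c2 = collections.Counter(out[i:i + 2] for i in range(len(out) - 1))
            assert c1 == c2
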