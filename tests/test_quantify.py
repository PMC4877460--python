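"""isomiR window matching, assignment policy, and profile bookkeeping."""
import numpy as np
import pytest

from mirgrad.quantify import (
    PrecursorIndex,
    dominant_isomir,
    match_read,
    quantify_sample,
)
from mirgrad.records import MatureArm, PrecursorRecord
from mirgrad.simulate import SimulationDesign, simulate_precursors, simulate_reads

from oracles import match_read_windows


@pytest.fixture(scope="module")
def simple_precursor():
    # 22-nt mature region placed at [10, 32) inside a 70-mer
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=70))
    arm = MatureArm("5p", 10, 32, "mir-simple-5p")
    return PrecursorRecord("pre-simple", seq, (arm,))


class TestMatchRead:
    def test_canonical_read_is_canonical_call(self, simple_precursor):
        mature = simple_precursor.mature_sequence("5p")
        call = match_read(mature, simple_precursor, "5p")
        assert (call.offset5, call.offset3, call.n_mismatches) == (0, 0, 0)
        assert call.is_canonical

    def test_three_prime_trimming(self, simple_precursor):
        mature = simple_precursor.mature_sequence("5p")
        call = match_read(mature[:-2], simple_precursor, "5p")
        assert (call.offset5, call.offset3, call.n_mismatches) == (0, -2, 0)

    def test_two_substitutions_fail(self, simple_precursor):
        mature = list(simple_precursor.mature_sequence("5p"))
        for pos in (5, 15):
            mature[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mature[pos]]
        read = "".join(mature)
        assert match_read(read, simple_precursor, "5p") is None
        assert match_read_windows(read, simple_precursor.sequence, 10, 32) is None

    def test_extension_is_positive_offset(self, simple_precursor):
        seq = simple_precursor.sequence
        read = seq[9:33]  # one extra base at each end
        call = match_read(read, simple_precursor, "5p")
        assert (call.offset5, call.offset3) == (1, 1)

    def test_empty_read_rejected(self, simple_precursor):
        with pytest.raises(ValueError):
            match_read("", simple_precursor, "5p")

    def test_out_of_range_length_rejected(self, simple_precursor):
        with pytest.raises(ValueError):
            match_read("ACGT", simple_precursor, "5p")

    def test_agrees_with_window_enumeration_oracle(self, rng, precursors):
        n_checked = 0
        for _ in range(300):
            pre = precursors[int(rng.integers(len(precursors)))]
            (arm,) = pre.mature_arms
            o5, o3 = int(rng.integers(-4, 5)), int(rng.integers(-4, 5))
            ws, we = arm.start - o5, arm.end + o3
            if ws < 0 or we > len(pre.sequence) or not (15 <= we - ws <= 35):
                continue
            read = list(pre.sequence[ws:we])
            if rng.random() < 0.5:  # sometimes plant 1-2 substitutions
                for pos in rng.choice(len(read), size=int(rng.integers(1, 3)), replace=False):
                    read[pos] = str(rng.choice([b for b in "ACGT" if b != read[pos]]))
            read = "".join(read)
            expected = match_read_windows(read, pre.sequence, arm.start, arm.end)
            call = match_read(read, pre, arm)
            got = None if call is None else (call.offset5, call.offset3, call.n_mismatches)
            assert got == expected
            n_checked += 1
        assert n_checked > 100


class TestQuantifySample:
    def test_identical_canonical_reads(self, simple_precursor):
        mature = simple_precursor.mature_sequence("5p")
        quant = quantify_sample([mature] * 100, [simple_precursor])
        assert quant.counts["mir-simple-5p"] == 100
        assert quant.profiles["mir-simple-5p"] == {(0, 0, 0): 100}
        assert quant.n_unassigned == 0

    def test_empty_read_set(self, simple_precursor):
        quant = quantify_sample([], [simple_precursor])
        assert (quant.counts == 0).all()
        assert quant.profiles == {}

    def test_profile_counts_conserve_matrix_counts(self, precursors):
        design = SimulationDesign(
            n_mirnas=20, n_gradient_up=0, n_gradient_down=0, library_size=1000, seed=6
        )
        reads, _ = simulate_reads(precursors, design)
        quant = quantify_sample(reads, precursors)
        for mature_id, profile in quant.profiles.items():
            assert sum(profile.values()) == quant.counts[mature_id]
        assert quant.counts.sum() + quant.n_unassigned == quant.n_reads

    def test_order_independence(self, precursors, rng):
        design = SimulationDesign(
            n_mirnas=20, n_gradient_up=0, n_gradient_down=0, library_size=400, seed=8
        )
        reads, _ = simulate_reads(precursors, design)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        a = quantify_sample(reads, precursors)
        b = quantify_sample(shuffled, precursors)
        assert (a.counts == b.counts).all()
        assert a.profiles == b.profiles

    def test_index_matches_bruteforce_assignment(self, precursors):
        design = SimulationDesign(
            n_mirnas=20, n_gradient_up=0, n_gradient_down=0,
            library_size=300, mismatch_rate=0.2, seed=10,
        )
        reads, _ = simulate_reads(precursors, design)
        with_index = quantify_sample(reads, precursors)
        # brute force: candidate generation replaced by "every arm"
        class AllArms(PrecursorIndex):
            def candidates(self, read):
                return self.arms

        brute = quantify_sample(reads, precursors, index=AllArms(precursors))
        assert (with_index.counts == brute.counts).all()
        assert with_index.profiles == brute.profiles

    def test_roundtrip_against_generator_truth(self, precursors):
        design = SimulationDesign(
            n_mirnas=20, n_gradient_up=0, n_gradient_down=0,
            library_size=1500, mismatch_rate=0.0, seed=12,
        )
        reads, truth = simulate_reads(precursors, design)
        by_id = {p.id: p for p in precursors}
        agree = 0
        for read, row in zip(reads, truth.itertuples()):
            pre = by_id[row.precursor]
            call = match_read(read.sequence, pre, pre.mature_arms[0])
            if call is not None and (
                call.offset5, call.offset3, call.n_mismatches
            ) == (row.offset5, row.offset3, row.n_mismatches):
                agree += 1
        assert agree / len(reads) >= 0.99

    def test_unmatchable_reads_counted_not_dropped(self, simple_precursor):
        quant = quantify_sample(["A" * 22, "C" * 22], [simple_precursor])
        assert quant.n_unassigned == 2
        assert quant.n_reads == 2

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            quantify_sample(["ACGT" * 5], [])


class TestDominantIsomir:
    def test_argmax(self):
        assert dominant_isomir({(0, 0, 0): 10, (0, -1, 0): 50}) == (0, -1, 0)

    def test_tie_prefers_canonical(self):
        assert dominant_isomir({(0, 0, 0): 10, (0, -1, 0): 10}) == (0, 0, 0)

    def test_tie_without_canonical_prefers_smallest_shift(self):
        assert dominant_isomir({(0, -2, 0): 7, (0, -1, 0): 7}) == (0, -1, 0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            dominant_isomir({})

    def test_generator_three_prime_bias_dominates(self, precursors):
        design = SimulationDesign(
            n_mirnas=20,
            n_gradient_up=0,
            n_gradient_down=0,
            library_size=10_000,
            isomir_offset_probs=({0: 1.0}, {-1: 0.6, 0: 0.4}),
            mismatch_rate=0.0,
            seed=13,
        )
        reads, _ = simulate_reads(precursors, design)
        quant = quantify_sample(reads, precursors)
        pooled: dict = {}
        for profile in quant.profiles.values():
            for key, count in profile.items():
                pooled[key] = pooled.get(key, 0) + count
        assert dominant_isomir(pooled) == (0, -1, 0)
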