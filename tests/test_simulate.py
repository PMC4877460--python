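"""Generator behavior: determinism, hairpin construction, planted truth."""
import collections

import numpy as np
import pandas as pd
import pytest

from mirgrad.records import reverse_complement
from mirgrad.simulate import (
    GRADIENT_DOWN,
    GRADIENT_UP,
    NULL,
    SimulationDesign,
    simulate_counts,
    simulate_precursors,
    simulate_qpcr,
    simulate_reads,
    truth_table,
)


def _min_hamming_alignment(needle: str, haystack: str) -> int:
    return min(
        sum(a != b for a, b in zip(needle, haystack[i : i + len(needle)]))
        for i in range(len(haystack) - len(needle) + 1)
    )


class TestPrecursors:
    def test_structure(self):
        for pre in simulate_precursors(10, seed=7):
            assert 60 <= len(pre.sequence) <= 90
            (arm,) = pre.mature_arms
            assert 20 <= len(arm) <= 23
            mature = pre.mature_sequence(arm)
            # the reverse complement of the mature region must align to
            # the opposite arm with at most the 2 planted point changes
            rc = reverse_complement(mature)
            if arm.arm == "5p":
                opposite = pre.sequence[arm.end :]
            else:
                opposite = pre.sequence[: arm.start]
            assert _min_hamming_alignment(rc, opposite) <= 2

    def test_deterministic_given_seed(self):
        a = simulate_precursors(5, seed=7)
        b = simulate_precursors(5, seed=7)
        assert [(p.id, p.sequence, p.mature_arms) for p in a] == [
            (p.id, p.sequence, p.mature_arms) for p in b
        ]

    def test_seed_changes_output(self):
        a = simulate_precursors(5, seed=7)
        b = simulate_precursors(5, seed=8)
        assert any(x.sequence != y.sequence for x, y in zip(a, b))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_precursors(0, seed=1)

    def test_length_weights_drive_mature_length(self):
        pres = simulate_precursors(8, seed=3, read_length_weights={22: 1.0})
        assert all(len(p.mature_arms[0]) == 22 for p in pres)


class TestReads:
    def test_degenerate_design_yields_canonical_reads(self, precursors):
        design = SimulationDesign(
            n_mirnas=20,
            n_gradient_up=0,
            n_gradient_down=0,
            library_size=500,
            isomir_offset_probs={0: 1.0},
            mismatch_rate=0.0,
            seed=5,
        )
        reads, truth = simulate_reads(precursors, design)
        by_id = {p.id: p for p in precursors}
        for read, row in zip(reads, truth.itertuples()):
            assert (row.offset5, row.offset3, row.n_mismatches) == (0, 0, 0)
            pre = by_id[row.precursor]
            assert read.sequence == pre.mature_sequence(row.mature_id)

    def test_byte_identical_fastq_given_seed(self, precursors):
        design = SimulationDesign(
            n_mirnas=20, n_gradient_up=0, n_gradient_down=0, library_size=200, seed=9
        )
        reads_a, _ = simulate_reads(precursors, design)
        reads_b, _ = simulate_reads(precursors, design)
        assert reads_a == reads_b

    def test_modal_read_length_is_22(self):
        pres = simulate_precursors(300, seed=1)
        design = SimulationDesign(
            n_mirnas=300, n_gradient_up=0, n_gradient_down=0, library_size=10_000, seed=1
        )
        reads, _ = simulate_reads(pres, design)
        hist = collections.Counter(len(r.sequence) for r in reads)
        assert hist.most_common(1)[0][0] == 22

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads([], SimulationDesign())

    def test_truth_matches_fastq_comment(self, precursors):
        from mirgrad.simulate import parse_read_truth

        design = SimulationDesign(
            n_mirnas=20, n_gradient_up=0, n_gradient_down=0, library_size=50, seed=2
        )
        reads, truth = simulate_reads(precursors, design)
        for read, row in zip(reads, truth.itertuples()):
            parsed = parse_read_truth(read.comment)
            assert parsed["mature_id"] == row.mature_id
            assert (parsed["offset5"], parsed["offset3"]) == (row.offset5, row.offset3)


class TestCounts:
    def test_gradient_truth_means(self):
        design = SimulationDesign(
            n_mirnas=5, n_gradient_up=1, n_gradient_down=1,
            baseline_mean=100.0, gradient_step=4.0, seed=0,
        )
        truth = truth_table(design)
        up = truth[truth["class"] == GRADIENT_UP].iloc[0]
        down = truth[truth["class"] == GRADIENT_DOWN].iloc[0]
        assert tuple(up[["mean_normal", "mean_adjacent", "mean_tumor"]]) == (100, 400, 1600)
        assert tuple(down[["mean_normal", "mean_adjacent", "mean_tumor"]]) == (100, 25, 6.25)
        # up rows strictly increasing, down strictly decreasing, null constant
        for _, row in truth.iterrows():
            means = tuple(row[["mean_normal", "mean_adjacent", "mean_tumor"]])
            if row["class"] == GRADIENT_UP:
                assert means[0] < means[1] < means[2]
            elif row["class"] == GRADIENT_DOWN:
                assert means[0] > means[1] > means[2]
            else:
                assert means[0] == means[1] == means[2]

    def test_all_null_when_no_gradients(self, null_design):
        _, truth = simulate_counts(null_design(n_mirnas=50))
        assert (truth["class"] == NULL).all()

    def test_law_of_large_numbers_on_null_means(self, null_design):
        matrix, _ = simulate_counts(null_design(n_mirnas=1000, seed=3))
        assert abs(matrix.column("normal").mean() - 100.0) < 1.0

    def test_reproducible_given_seed(self, null_design):
        a, _ = simulate_counts(null_design(n_mirnas=100, seed=11))
        b, _ = simulate_counts(null_design(n_mirnas=100, seed=11))
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_library_size_is_column_total(self, null_design):
        matrix, _ = simulate_counts(null_design(n_mirnas=100, seed=4))
        assert (matrix.library_size == matrix.counts.sum(axis=0)).all()

    def test_depth_factors_tilt_totals(self, null_design):
        matrix, _ = simulate_counts(
            null_design(n_mirnas=500, seed=5), depth_factors={"tumor": 2.0}
        )
        ratio = matrix.library_size["tumor"] / matrix.library_size["normal"]
        assert 1.8 < ratio < 2.2


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mirnas": 0},
            {"n_gradient_up": 150, "n_gradient_down": 100},
            {"baseline_mean": 0.0},
            {"gradient_step": 1.5},
            {"library_size": 0},
            {"mismatch_rate": 1.5},
            {"read_length_weights": {22: 0.5}},
            {"isomir_offset_probs": {0: 0.5, 5: 0.5}},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationDesign(**kwargs)


class TestQpcr:
    def _truth(self, mean_tumor, mean_adjacent=100.0, mean_normal=100.0):
        return pd.DataFrame(
            {
                "class": ["x"],
                "mean_normal": [mean_normal],
                "mean_adjacent": [mean_adjacent],
                "mean_tumor": [mean_tumor],
            },
            index=pd.Index(["mir-x"], name="mirna_id"),
        )

    def test_noise_free_fourfold_shifts_dct_by_two(self):
        from mirgrad.qpcr import sample_delta_ct

        table = simulate_qpcr(self._truth(400.0), n_samples=2, noise_sd=0.0, seed=0)
        dct = sample_delta_ct(table)
        by_group = dct.groupby("group")["delta_ct"].mean()
        assert by_group["tumor"] == pytest.approx(by_group["normal"] - 2.0)

    def test_noise_free_null_gives_zero_ddct(self):
        from mirgrad.qpcr import analyze_qpcr

        table = simulate_qpcr(self._truth(100.0), n_samples=3, noise_sd=0.0, seed=0)
        _, contrasts = analyze_qpcr(table)
        row = contrasts[(contrasts.case == "tumor") & (contrasts.control == "normal")]
        assert row["ddct"].iloc[0] == pytest.approx(0.0)
        assert row["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_eightfold_change_recovered_within_20pct(self):
        from mirgrad.qpcr import analyze_qpcr

        table = simulate_qpcr(self._truth(800.0), n_samples=9, noise_sd=0.1, seed=7)
        _, contrasts = analyze_qpcr(table)
        fold = contrasts[
            (contrasts.case == "tumor") & (contrasts.control == "normal")
        ]["fold_change"].iloc[0]
        assert 0.8 * 8 <= fold <= 1.2 * 8

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(self._truth(100.0), n_samples=3, noise_sd=-0.1, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(self._truth(100.0), n_samples=1, noise_sd=0.1, seed=0)
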