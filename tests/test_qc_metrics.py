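"""Per-read and per-position statistics, and the two averaging modes."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seqscope.qc_metrics import (
    EXACT_POSITIONS,
    PositionBinner,
    PositionProfile,
    ReadSummaries,
    accumulate,
    gc_percent,
    phred_to_error,
    read_mean_quality_arithmetic,
    read_mean_quality_expected_error,
)

from conftest import make_record


class TestPhredConversions:
    @pytest.mark.parametrize("q,err", [(0, 1.0), (10, 0.1), (20, 0.01), (30, 0.001)])
    def test_phred_to_error(self, q, err):
        assert phred_to_error(q) == pytest.approx(err)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            phred_to_error(-1)

    @pytest.mark.parametrize(
        "quals,expected",
        [
            ([10, 10, 10], 10.0),
            ([0], 0.0),
            # -10*log10((0.1 + 0.01)/2) = -10*log10(0.055)
            ([10, 20], -10 * math.log10(0.055)),
        ],
    )
    def test_expected_error_mean(self, quals, expected):
        assert read_mean_quality_expected_error(quals) == pytest.approx(expected)

    def test_arithmetic_mean(self):
        assert read_mean_quality_arithmetic([10, 20]) == 15.0
        assert read_mean_quality_arithmetic([10, 10, 10]) == 10.0

    @pytest.mark.parametrize("fn", [read_mean_quality_expected_error,
                                    read_mean_quality_arithmetic])
    def test_empty_rejected(self, fn):
        with pytest.raises(ValueError):
            fn([])

    @given(st.lists(st.integers(0, 93), min_size=1, max_size=300))
    def test_arithmetic_never_below_expected_error(self, quals):
        """Jensen's inequality: the arithmetic Phred mean overestimates,
        with equality exactly when all scores are equal."""
        arith = read_mean_quality_arithmetic(quals)
        ee = read_mean_quality_expected_error(quals)
        assert arith >= ee - 1e-9
        if len(set(quals)) == 1:
            assert arith == pytest.approx(ee)
        elif max(quals) - min(quals) >= 1:
            assert arith > ee


class TestGCPercent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 50.0), ("AAAA", 0.0), ("GCNGC", 100.0), ("GGGG", 100.0)],
    )
    def test_values(self, seq, expected):
        assert gc_percent(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq", ["", "NNNN"])
    def test_undefined(self, seq):
        assert gc_percent(seq) is None


class TestPositionBinning:
    def test_exact_below_500_geometric_after(self):
        binner = PositionBinner()
        starts = binner.starts()
        assert list(starts[:EXACT_POSITIONS]) == list(range(EXACT_POSITIONS))
        widths = np.diff(starts[EXACT_POSITIONS:])
        assert (widths >= 1).all()
        # geometric growth (allowing integer-rounding jitter bin to bin)
        assert (widths[10:] >= widths[:-10]).all()
        assert widths[-1] > widths[0]

    def test_bins_cover_all_positions(self):
        binner = PositionBinner()
        bins = binner.bins(100_000)
        assert len(bins) == 100_000
        assert (np.diff(bins) >= 0).all()
        assert bins[0] == 0


class TestAccumulate:
    def test_single_read_counts(self):
        profile, summaries = PositionProfile(), ReadSummaries()
        rec = make_record("ACGT", np.array([40, 40, 40, 40], dtype=np.uint8))
        accumulate(rec, profile, summaries)
        assert profile.base_counts[0].tolist() == [1, 0, 0, 0, 0]
        assert profile.base_counts[3].tolist() == [0, 0, 0, 1, 0]
        assert profile.qual_sum[0] == 40
        assert summaries.length_hist[4] == 1

    def test_identical_reads_concentrate_histograms(self):
        profile, summaries = PositionProfile(), ReadSummaries()
        rec = make_record("ACGT", np.array([20, 20, 20, 20], dtype=np.uint8))
        for _ in range(100):
            accumulate(rec, profile, summaries)
        assert summaries.length_hist == {4: 100}
        assert summaries.q_hist_arithmetic[20] == 100
        assert summaries.q_hist_arithmetic.sum() == 100
        assert summaries.gc_hist[50] == 100

    def test_conservation_and_monotone_coverage(self, small_library):
        records, _ = small_library
        profile, summaries = PositionProfile(), ReadSummaries()
        for rec in records:
            accumulate(rec, profile, summaries)
        n = len(records)
        assert sum(summaries.length_hist.values()) == n
        assert summaries.gc_hist.sum() + summaries.gc_undefined == n
        assert summaries.q_hist_expected_error.sum() + summaries.empty_reads == n
        assert summaries.q_hist_arithmetic.sum() + summaries.empty_reads == n
        cov = profile.coverage
        assert (np.diff(cov) <= 0).all()  # reads only get shorter

    def test_variable_lengths_column_sums(self, rng):
        profile, summaries = PositionProfile(), ReadSummaries()
        lengths = [5, 10, 10, 3]
        for L in lengths:
            seq = "".join(rng.choice(list("ACGT"), size=L))
            accumulate(make_record(seq), profile, summaries)
        cov = profile.coverage
        for pos in range(10):
            assert cov[pos] == sum(1 for L in lengths if L > pos)
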