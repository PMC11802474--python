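"""Fragment sampling, counting, canonical k-mers and Smith-Waterman."""
import functools
import io
import itertools

import numpy as np
import pytest
from Bio import Align

from seqscope.config import QCConfig
from seqscope.overrepresented import (
    FragmentTable,
    build_contaminant_index,
    bundled_contaminant_db,
    canonical_kmer,
    flag_overrepresented,
    identify_fragment,
    sample_fragments,
    smith_waterman,
    table_update,
)
from seqscope.records import reverse_complement

SCORES = (2, -3, -5, -2)


class TestSampleFragments:
    def test_unsampled_read_yields_nothing(self, cfg):
        assert sample_fragments("A" * 100, 1, cfg) == []

    def test_two_fragments_from_42bp(self, cfg):
        seq = "AC" * 21  # 42 bp
        frags = sample_fragments(seq, 0, cfg)
        assert frags == [seq[:21], seq[21:]]

    def test_n_fragments_skipped(self, cfg):
        seq = "A" * 21 + "N" + "C" * 20 + "G" * 21
        frags = sample_fragments(seq, 0, cfg)
        assert frags == ["A" * 21, "G" * 21]

    def test_long_read_capped_at_eight(self, cfg):
        frags = sample_fragments("ACGTA" * 1000, 0, cfg)  # 5000 bp
        assert len(frags) == cfg.max_fragments_per_read

    def test_sampled_read_count(self, cfg):
        table = FragmentTable(cfg)
        for i in range(10_000):
            table.add_read("ACGT" * 10, i)
        assert table.sampled_reads == 1250  # ceil(10^4 / 8)


class TestFragmentTable:
    def test_cap_walkthrough(self):
        cfg = QCConfig(fragment_store_cap=2)
        table = FragmentTable(cfg)
        table_update(table, ["a", "b", "c", "a"])
        assert table.counts == {"a": 2, "b": 1}
        assert table.table_saturated

    def test_exact_without_saturation(self, cfg):
        table = FragmentTable(cfg)
        table.update(["x", "y", "x"])
        assert table.counts == {"x": 2, "y": 1}
        assert not table.table_saturated

    def test_distinct_stream_fills_to_cap(self):
        cfg = QCConfig(fragment_store_cap=100)
        table = FragmentTable(cfg)
        table.update([f"frag{i}" for i in range(500)])
        assert len(table.counts) == 100


class TestFlagging:
    def _table_with(self, cfg, counts, sampled):
        table = FragmentTable(cfg)
        table.counts = dict(counts)
        table.sampled_reads = sampled
        return table

    def test_above_threshold_flagged(self, cfg):
        table = self._table_with(cfg, {"AAA": 11}, 10_000)  # 0.11% > 0.1%
        assert flag_overrepresented(table, cfg) == [("AAA", 11, 11 / 10_000)]

    def test_exactly_at_threshold_not_flagged(self, cfg):
        table = self._table_with(cfg, {"AAA": 10}, 10_000)  # exactly 0.1%
        assert flag_overrepresented(table, cfg) == []

    def test_sort_order(self, cfg):
        table = self._table_with(cfg, {"B": 50, "A": 50, "C": 90}, 1000)
        assert [f for f, _, _ in flag_overrepresented(table, cfg)] == ["C", "A", "B"]


class TestCanonicalKmers:
    def test_involution_and_rc_invariance_exhaustive(self):
        for k in (1, 2, 3, 5, 6):
            for kmer in map("".join, itertools.product("ACGT", repeat=k)):
                canon = canonical_kmer(kmer)
                assert canonical_kmer(canon) == canon
                assert canonical_kmer(reverse_complement(kmer)) == canon

    def test_palindrome_and_homopolymer(self):
        assert canonical_kmer("ACGT") == "ACGT"
        assert canonical_kmer("TTTT") == "AAAA"


class TestContaminantIndex:
    def test_kmers_indexed_canonically(self):
        cfg = QCConfig(kmer_size=4)
        fasta = io.StringIO(">e1 test\nAAAACGT\n")
        db = build_contaminant_index(fasta, cfg)
        assert "AAAA" in db.kmer_index
        assert "ACGT" in db.kmer_index  # RC-palindromic window
        # TTTT windows elsewhere would land under AAAA too
        db2 = build_contaminant_index(io.StringIO(">e2 x\nGGTTTTGG\n"),
                                      QCConfig(kmer_size=4))
        assert "AAAA" in db2.kmer_index

    def test_empty_fasta_rejected(self, cfg):
        with pytest.raises(ValueError):
            build_contaminant_index(io.StringIO(""), cfg)

    def test_bundled_db_loads(self, cfg):
        db = bundled_contaminant_db(cfg)
        assert len(db.entries) == 20
        assert all(seq for _, _, seq in db.entries)


# --- Smith-Waterman oracles --------------------------------------------------


def brute_force_local(a: str, b: str, scores=SCORES) -> int:
    """Independent oracle: best local score by enumerating all alignments
    of all substring pairs (memoised recursion over edit operations, not
    the Gotoh matrices)."""
    match, mismatch, gap_open, gap_extend = scores

    @functools.lru_cache(maxsize=None)
    def best_global(x: str, y: str, last: str) -> int:
        if not x and not y:
            return 0
        options = []
        if x and y:
            s = match if x[0] == y[0] else mismatch
            options.append(s + best_global(x[1:], y[1:], "M"))
        if x:
            g = gap_extend if last == "U" else gap_open
            options.append(g + best_global(x[1:], y, "U"))
        if y:
            g = gap_extend if last == "L" else gap_open
            options.append(g + best_global(x, y[1:], "L"))
        return max(options)

    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, best_global(a[i:j], b[k:l], "M"))
    return best


class TestSmithWaterman:
    def test_perfect_self_alignment(self):
        res = smith_waterman("ACGTACGT", "ACGTACGT", SCORES)
        assert res.score == 16 and res.identity == 1.0

    def test_no_positive_cell_is_absent(self):
        assert smith_waterman("AAAA", "GGGG", SCORES) is None

    def test_exact_21mer_worked_example(self, rng):
        entry = "".join(rng.choice(list("ACGT"), size=100))
        frag = entry[40:61]
        res = smith_waterman(frag, entry, SCORES)
        assert res.score == 42  # 21 matches at +2
        assert res.identity == 1.0
        assert res.target_span == (40, 61)

    def test_one_mismatch_21mer_worked_example(self, rng):
        entry = "".join(rng.choice(list("ACGT"), size=100))
        frag = list(entry[40:61])
        frag[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[10]]
        res = smith_waterman("".join(frag), entry, SCORES)
        assert res.identity == pytest.approx(20 / 21)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", SCORES)

    def test_symmetry(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 15)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 15)))
            sa = smith_waterman(a, b, SCORES)
            sb = smith_waterman(b, a, SCORES)
            assert (sa.score if sa else 0) == (sb.score if sb else 0)

    def test_agrees_with_brute_force_enumeration(self, rng):
        for _ in range(150):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            res = smith_waterman(a, b, SCORES)
            assert (res.score if res else 0) == brute_force_local(a, b)

    def test_agrees_with_biopython_local_aligner(self, rng):
        aligner = Align.PairwiseAligner(
            mode="local", match_score=2, mismatch_score=-3,
            open_gap_score=-5, extend_gap_score=-2,
        )
        for _ in range(300):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
            res = smith_waterman(a, b, SCORES)
            assert (res.score if res else 0) == aligner.score(a, b)


class TestIdentifyFragment:
    def test_exact_substring_identified(self, cfg):
        db = bundled_contaminant_db(cfg)
        entry_id, _, seq = db.entries[3]
        frag = seq[10:31]
        hit = identify_fragment(frag, db, cfg)
        assert hit is not None
        assert hit.target_id == entry_id
        assert hit.identity == 1.0
        assert hit.score == 42

    def test_reverse_complement_fragment_identified(self, cfg):
        db = bundled_contaminant_db(cfg)
        entry_id, _, seq = db.entries[5]
        frag = reverse_complement(seq[20:41])
        hit = identify_fragment(frag, db, cfg)
        assert hit is not None and hit.target_id == entry_id
        assert hit.strand == "-"

    def test_too_short_fragment_rejected(self, cfg):
        with pytest.raises(ValueError):
            identify_fragment("ACGT", bundled_contaminant_db(cfg), cfg)

    def test_random_fragments_rarely_hit(self, cfg, rng):
        db = bundled_contaminant_db(cfg)
        hits = sum(
            identify_fragment(
                "".join(rng.choice(list("ACGT"), size=21)), db, cfg
            )
            is not None
            for _ in range(1000)
        )
        assert hits / 1000 < 0.01
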