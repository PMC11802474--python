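"""Fingerprinting and the adaptive hash-sampling duplication sketch."""
from collections import Counter

import numpy as np
import pytest

from seqscope.config import QCConfig
from seqscope.duplication import (
    DupSketch,
    EMPTY_FINGERPRINT,
    estimate_duplication,
    fingerprint,
    sketch_insert,
    splitmix64,
)
from seqscope.fixtures import LibrarySpec, generate_sequences


class TestSplitmix64:
    def test_published_reference_values(self):
        # first two outputs of the SplitMix64 sequence for seed 0
        assert splitmix64(0) == 0xE220A8397B1DCDAF
        assert splitmix64(1) == 0x910A2DEC89025CC1

    def test_stays_in_64_bits(self):
        assert 0 <= splitmix64((1 << 64) - 1) < (1 << 64)


class TestFingerprint:
    def test_identical_reads_identical_fingerprints(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        assert fingerprint(seq) == fingerprint(seq)

    def test_all_a_window_reads_collide(self):
        # reads whose sampled windows are all A share a fingerprint
        assert fingerprint("A" * 16) == fingerprint("A" * 16)
        assert fingerprint("A" * 200).bits == fingerprint("A" * 300).bits

    def test_short_read_flag_and_padding(self):
        fp = fingerprint("ACGT")
        assert fp.short_read_flag
        assert fp == fingerprint("ACGT")  # deterministic
        assert fingerprint("ACGT") != fingerprint("CGTA")

    def test_empty_read_is_distinguished(self):
        assert fingerprint("") is EMPTY_FINGERPRINT
        sketch = DupSketch(10)
        sketch.insert(fingerprint(""))
        assert sketch.empty_reads == 1

    def test_n_maps_to_a(self):
        assert fingerprint("N" * 16).bits == fingerprint("A" * 16).bits

    def test_collision_rate_on_distinct_reads(self, rng):
        codes = rng.integers(0, 4, size=(10_000, 150))
        bases = np.array(list("ACGT"))
        fps = {fingerprint("".join(bases[c])).bits for c in codes}
        assert len(fps) >= 0.99 * 10_000


class TestSketch:
    def test_exact_counts_below_capacity(self, rng):
        sketch = DupSketch(capacity=10_000)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(300)]
        stream = seqs + seqs[:100]  # 100 doubles
        truth = Counter(fingerprint(s).bits for s in stream)
        for s in stream:
            sketch_insert(sketch, fingerprint(s))
        assert sketch.depth == 0
        assert sketch.tracked == dict(truth)

    def test_same_fingerprint_counted(self):
        sketch = DupSketch(10)
        fp = fingerprint("ACGT" * 10)
        for _ in range(5):
            sketch.insert(fp)
        assert sketch.tracked[fp.bits] == 5

    def test_eviction_respects_capacity_and_criterion(self, rng):
        sketch = DupSketch(capacity=1000)
        codes = rng.integers(0, 4, size=(20_000, 60))
        bases = np.array(list("ACGT"))
        for c in codes:
            sketch.insert(fingerprint("".join(bases[c])))
        assert len(sketch.tracked) <= 1000
        assert sketch.depth > 0
        mask = (1 << sketch.depth) - 1
        assert all(splitmix64(bits) & mask == 0 for bits in sketch.tracked)


class TestEstimate:
    def test_all_unique_no_eviction(self, rng):
        sketch = DupSketch(capacity=100_000)
        seqs, _ = generate_sequences(LibrarySpec(n_reads=2000, seed=20))
        for s in seqs:
            sketch.insert(fingerprint(s))
        prof = estimate_duplication(sketch)
        assert prof.exact
        assert prof.remaining_fraction == pytest.approx(1.0)
        assert prof.multiplicity[1] == 2000

    def test_everything_doubled(self, rng):
        sketch = DupSketch(capacity=100_000)
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(500)]
        for s in seqs + seqs:
            sketch.insert(fingerprint(s))
        prof = estimate_duplication(sketch)
        assert prof.remaining_fraction == pytest.approx(0.5)
        assert prof.multiplicity[2] == 500
        assert prof.multiplicity[1] == 0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            estimate_duplication(DupSketch(10))

    def test_matches_exact_oracle_under_eviction(self):
        """Hash-sampling estimate vs brute-force distinct count, 20% dups."""
        seqs, manifest = generate_sequences(
            LibrarySpec(n_reads=50_000, duplicate_fraction=0.2, seed=21)
        )
        sketch = DupSketch(capacity=1000)
        exact = set()
        for s in seqs:
            fp = fingerprint(s)
            sketch.insert(fp)
            exact.add(fp.bits)
        prof = estimate_duplication(sketch)
        assert not prof.exact
        truth = len(exact) / len(seqs)
        # one stream: allow ~3 sd of the hash-sampling estimator at this capacity
        assert prof.remaining_fraction == pytest.approx(truth, abs=0.1)

    def test_order_insensitivity(self, rng):
        seqs, _ = generate_sequences(
            LibrarySpec(n_reads=20_000, duplicate_fraction=0.5, seed=22)
        )
        estimates = []
        for order_seed in (0, 1):
            perm = np.random.default_rng(order_seed).permutation(len(seqs))
            sketch = DupSketch(capacity=500)
            for i in perm:
                sketch.insert(fingerprint(seqs[i]))
            estimates.append(estimate_duplication(sketch).remaining_fraction)
        assert abs(estimates[0] - estimates[1]) < 0.02
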