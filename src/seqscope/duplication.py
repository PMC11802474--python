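"""Duplication profiling by fingerprint hash-sampling.

Each read is reduced to a 16 bp fingerprint (two 8-mers sampled from
fixed offsets, 2 bits per base).  Fingerprints are counted in a sketch
that adaptively subsamples by hash value: at depth ``d`` a fingerprint
is tracked iff the low ``d`` bits of its 64-bit mixed hash are zero.
When the tracked set outgrows its capacity the depth increments and
entries failing the new criterion are evicted.  Because the criterion
depends only on the fingerprint, a surviving fingerprint has been
tracked since the start and its count is exact; multiplying surviving
counts by ``2**d`` therefore yields an unbiased estimate of the full
multiset — the distinct-count estimate is accurate in bounded memory,
unlike first-N-reads schemes, which overestimate unique reads.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .config import QCConfig

_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}  # N collapses to A, deterministic

#: multiplicities above this are pooled into one ">=" bucket
MULTIPLICITY_CAP = 16

_MASK64 = (1 << 64) - 1


def splitmix64(x: int) -> int:
    """SplitMix64 finalizer: a fixed, published 64-bit mixing function.

    Fully deterministic across platforms and runs (no per-run salt).
    """
    z = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


@dataclass(frozen=True)
class Fingerprint:
    bits: int             # 16 bases packed at 2 bits/base
    short_read_flag: bool  # read shorter than the fingerprint span
    empty: bool = False


EMPTY_FINGERPRINT = Fingerprint(bits=0, short_read_flag=True, empty=True)


def _pack(seq16: str) -> int:
    bits = 0
    for c in seq16:
        bits = (bits << 2) | _BASE_BITS[c]
    return bits


def fingerprint(record_or_seq, cfg: QCConfig | None = None) -> Fingerprint:
    """16 bp fingerprint from fixed read offsets.

    The front 8-mer starts at ``f = min(64, max(0, L-16))`` — skipping
    the first 64 bases of long reads, where adapters and barcodes live —
    and the back 8-mer ends ``f`` bases before the read end.  Reads
    shorter than 16 bases use the whole read left-padded with A;
    identical reads always map to identical fingerprints.
    """
    seq = record_or_seq if isinstance(record_or_seq, str) else record_or_seq.sequence
    L = len(seq)
    if L == 0:
        return EMPTY_FINGERPRINT
    if L < 16:
        return Fingerprint(bits=_pack("A" * (16 - L) + seq), short_read_flag=True)
    f = min(64, L - 16)
    front = seq[f : f + 8]
    back = seq[L - f - 8 : L - f]
    return Fingerprint(bits=_pack(front + back), short_read_flag=False)


class DupSketch:
    """Adaptive hash-sampled fingerprint multiset."""

    def __init__(self, capacity: int = 100_000):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.tracked: dict[int, int] = {}
        self.depth = 0
        self.total_reads = 0
        self.empty_reads = 0

    def _passes(self, hashed: int) -> bool:
        return hashed & ((1 << self.depth) - 1) == 0

    def insert(self, fp: Fingerprint) -> None:
        self.total_reads += 1
        if fp.empty:
            self.empty_reads += 1
            return
        hashed = splitmix64(fp.bits)
        if not self._passes(hashed):
            return
        self.tracked[fp.bits] = self.tracked.get(fp.bits, 0) + 1
        while len(self.tracked) > self.capacity:
            self.depth += 1
            self.tracked = {
                bits: count
                for bits, count in self.tracked.items()
                if self._passes(splitmix64(bits))
            }

    def estimate(self) -> "DuplicationProfile":
        if self.total_reads == 0:
            raise ValueError("cannot estimate duplication from zero reads")
        scale = 1 << self.depth
        distinct_est = len(self.tracked) * scale
        hist = Counter()
        for count in self.tracked.values():
            hist[min(count, MULTIPLICITY_CAP)] += 1
        multiplicity = {m: hist.get(m, 0) * scale for m in range(1, MULTIPLICITY_CAP + 1)}
        return DuplicationProfile(
            remaining_fraction=distinct_est / self.total_reads,
            estimated_distinct=distinct_est,
            multiplicity=multiplicity,
            depth=self.depth,
            tracked=len(self.tracked),
            total_reads=self.total_reads,
            exact=(self.depth == 0),
        )


@dataclass
class DuplicationProfile:
    """Estimated duplication profile.

    ``remaining_fraction`` is the estimated fraction of reads left after
    perfect deduplication; ``multiplicity[m]`` the estimated number of
    distinct sequences observed exactly ``m`` times (``m = 16`` pools
    all higher multiplicities).  After eviction both are hash-sample
    estimates; ``exact`` records whether eviction ever triggered.
    """

    remaining_fraction: float
    estimated_distinct: int
    multiplicity: dict[int, int]
    depth: int
    tracked: int
    total_reads: int
    exact: bool


def sketch_insert(sketch: DupSketch, fp: Fingerprint) -> DupSketch:
    sketch.insert(fp)
    return sketch


def estimate_duplication(sketch: DupSketch) -> DuplicationProfile:
    return sketch.estimate()
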