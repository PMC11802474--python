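"""Paired-end overlap detection: insert size and read-through adapters.

When the DNA insert is shorter than twice the read length the two mates
overlap; aligning R1 against the reverse complement of R2 (ungapped, at
every offset) recovers the insert size directly.  When the insert is
shorter than a read, each mate reads through into adapter, whose start
position equals the insert size — this is the paired-end route to
adapter detection, more sensitive than probe search because it needs no
prior knowledge of the adapter sequence.

Offsets are enumerated exhaustively; the mismatch count is plain
(quality-unaware).  An offset qualifies when the overlap is at least
``min_overlap`` bases with a mismatch fraction at most
``max_overlap_error``; among qualifying offsets the one with the most
matching bases wins, ties broken toward the smallest insert size.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import QCConfig
from .records import ReadPair, reverse_complement


@dataclass
class OverlapResult:
    insert_size: int | None
    adapter_start_r1: int | None
    adapter_start_r2: int | None
    overlap_len: int
    mismatches: int

    @property
    def detected(self) -> bool:
        return self.insert_size is not None


_NO_OVERLAP = OverlapResult(None, None, None, 0, 0)


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_overlap(pair: ReadPair, cfg: QCConfig | None = None) -> OverlapResult:
    """Best ungapped overlap between R1 and reverse-complemented R2.

    For a candidate insert size ``I`` (fragment coordinates: R1 covers
    ``[0, len1)``, RC(R2) covers ``[I-len2, I)``) the overlap is the
    intersection of the two intervals.  All ``I`` are scored in one
    vectorised pass; absence of a qualifying offset is a valid result.
    """
    cfg = cfg or QCConfig()
    n1, n2 = len(pair.r1), len(pair.r2)
    if n1 == 0 or n2 == 0:
        return _NO_OVERLAP
    r1 = _to_array(pair.r1.sequence)
    rc2 = _to_array(reverse_complement(pair.r2.sequence))

    # pad R1 with a sentinel that never equals a base; window at padded
    # offset I aligns RC(R2) with fragment coordinate I - n2
    padded = np.full(n1 + 2 * n2, ord("#"), dtype=np.uint8)
    padded[n2 : n2 + n1] = r1
    windows = sliding_window_view(padded, n2)          # shape (n1+n2+1, n2)
    matches = (windows == rc2).sum(axis=1)             # per candidate I
    inserts = np.arange(len(windows))                  # I = window offset
    overlap_len = np.minimum(n1, inserts) - np.maximum(0, inserts - n2)
    overlap_len = np.maximum(overlap_len, 0)
    mismatches = overlap_len - matches

    ok = (
        (inserts >= 1)
        & (overlap_len >= cfg.min_overlap)
        & (mismatches <= cfg.max_overlap_error * overlap_len)
    )
    if not ok.any():
        return _NO_OVERLAP
    cand = np.flatnonzero(ok)
    best = cand[np.argmax(matches[cand])]  # argmax → first max → smallest I on ties
    insert = int(inserts[best])
    return OverlapResult(
        insert_size=insert,
        adapter_start_r1=insert if insert < n1 else None,
        adapter_start_r2=insert if insert < n2 else None,
        overlap_len=int(overlap_len[best]),
        mismatches=int(mismatches[best]),
    )


class InsertSizeHistogram:
    """Histogram over detected insert sizes plus an undetermined bin."""

    def __init__(self) -> None:
        self.counts: Counter = Counter()
        self.undetermined = 0
        self.with_adapter = 0
        self.total_pairs = 0

    def add(self, result: OverlapResult) -> None:
        self.total_pairs += 1
        if not result.detected:
            self.undetermined += 1
            return
        self.counts[result.insert_size] += 1
        if result.adapter_start_r1 is not None or result.adapter_start_r2 is not None:
            self.with_adapter += 1

    @property
    def adapter_fraction(self) -> float:
        return self.with_adapter / self.total_pairs if self.total_pairs else 0.0

    def mode(self) -> int | None:
        if not self.counts:
            return None
        return max(self.counts, key=lambda k: (self.counts[k], -k))


def insert_size_histogram(results) -> InsertSizeHistogram:
    hist = InsertSizeHistogram()
    for res in results:
        hist.add(res)
    return hist
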