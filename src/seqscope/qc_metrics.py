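"""Generic per-position and per-read statistics.

Per-read quality is summarised in two modes:

* **expected-error** (the default, statistically correct one): per-base
  Phred scores are converted to error probabilities, averaged, and the
  mean error converted back to a Phred value,
  ``Q_read = -10 * log10( mean_i 10^(-q_i / 10) )``;
* **arithmetic**: the plain mean of the Phred scores, which by Jensen's
  inequality never falls below the expected-error value and therefore
  systematically overestimates read quality.  It is kept as an explicit
  comparison mode.

Per-position profiles are exact per base up to position 500; beyond
that, positions fall into geometrically growing bins (width x1.1 per
bin) so ultra-long nanopore reads use bounded memory.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

MAX_PHRED = 93
EXACT_POSITIONS = 500  # per-base resolution below this; geometric bins beyond
_BIN_GROWTH = 1.1

_BASE_ORDER = "ACGTN"
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASE_ORDER):
    _BASE_CODE[ord(_b)] = _i


def phred_to_error(q: float) -> float:
    """Error probability for Phred score *q*: ``10**(-q/10)``."""
    if q < 0:
        raise ValueError(f"negative Phred score: {q}")
    return 10.0 ** (-q / 10.0)


def read_mean_quality_expected_error(qualities) -> float:
    """Mean read quality via the expected error rate.

    Returns ``-10*log10(mean_i 10**(-q_i/10))``.
    """
    q = np.asarray(qualities, dtype=np.float64)
    if q.size == 0:
        raise ValueError("cannot average an empty quality list")
    if q.min() < 0:
        raise ValueError("negative Phred score")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def read_mean_quality_arithmetic(qualities) -> float:
    """Plain arithmetic mean of the Phred scores (overestimates quality)."""
    q = np.asarray(qualities, dtype=np.float64)
    if q.size == 0:
        raise ValueError("cannot average an empty quality list")
    return float(q.mean())


def gc_percent(sequence: str) -> float | None:
    """GC content in percent; N excluded entirely; ``None`` if undefined
    (empty or all-N read)."""
    counts = Counter(sequence)
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        return None
    return 100.0 * (counts["G"] + counts["C"]) / acgt


def _build_bin_starts(limit: int) -> np.ndarray:
    """Bin start positions: 0..EXACT_POSITIONS-1 per base, then widths
    growing by x1.1 per bin, covering positions up to *limit*."""
    starts = list(range(EXACT_POSITIONS))
    edge, width = float(EXACT_POSITIONS), 1.0
    while edge <= limit:
        starts.append(int(round(edge)))
        width *= _BIN_GROWTH
        edge += width
    # de-duplicate rounded edges, keep strictly increasing
    out = [starts[0]]
    for s in starts[1:]:
        if s > out[-1]:
            out.append(s)
    return np.asarray(out, dtype=np.int64)


class PositionBinner:
    """Maps read positions to profile bins, growing on demand."""

    def __init__(self) -> None:
        self._starts = _build_bin_starts(EXACT_POSITIONS)
        self._lookup = np.empty(0, dtype=np.int64)
        self._rebuild_lookup(1024)

    def _rebuild_lookup(self, max_len: int) -> None:
        while self._starts[-1] <= max_len:
            self._starts = _build_bin_starts(2 * max_len)
        positions = np.arange(max_len, dtype=np.int64)
        self._lookup = np.searchsorted(self._starts, positions, side="right") - 1

    def bins(self, length: int) -> np.ndarray:
        """Bin index for each position 0..length-1."""
        if length > len(self._lookup):
            self._rebuild_lookup(2 * length)
        return self._lookup[:length]

    @property
    def n_bins(self) -> int:
        return len(self._starts)

    def bin_start(self, index: int) -> int:
        return int(self._starts[index])

    def starts(self) -> np.ndarray:
        return self._starts.copy()


class PositionProfile:
    """Per-position base composition and quality aggregates."""

    def __init__(self) -> None:
        self.binner = PositionBinner()
        n = 64
        self.base_counts = np.zeros((n, 5), dtype=np.int64)   # A C G T N
        self.qual_sum = np.zeros(n, dtype=np.float64)         # sum of Phred
        self.err_sum = np.zeros(n, dtype=np.float64)          # sum of 10^(-q/10)
        self.max_bin = -1

    def _ensure(self, nbins: int) -> None:
        if nbins <= len(self.qual_sum):
            return
        grow = max(nbins, 2 * len(self.qual_sum))
        self.base_counts = np.vstack(
            [self.base_counts, np.zeros((grow - len(self.qual_sum), 5), np.int64)]
        )
        self.qual_sum = np.concatenate(
            [self.qual_sum, np.zeros(grow - len(self.qual_sum))]
        )
        self.err_sum = np.concatenate(
            [self.err_sum, np.zeros(grow - len(self.err_sum))]
        )

    def add(self, sequence: str, qualities: np.ndarray) -> None:
        L = len(sequence)
        if L == 0:
            return
        bins = self.binner.bins(L)
        self._ensure(int(bins[-1]) + 1)
        codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
        np.add.at(self.base_counts, (bins, codes), 1)
        q = qualities.astype(np.float64)
        np.add.at(self.qual_sum, bins, q)
        np.add.at(self.err_sum, bins, 10.0 ** (-q / 10.0))
        self.max_bin = max(self.max_bin, int(bins[-1]))

    @property
    def coverage(self) -> np.ndarray:
        """Base observations per bin (= column sum of base_counts)."""
        return self.base_counts[: self.max_bin + 1].sum(axis=1)

    def mean_phred(self) -> np.ndarray:
        """Arithmetic mean Phred per bin."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.qual_sum[: self.max_bin + 1] / cov, np.nan)

    def phred_of_mean_error(self) -> np.ndarray:
        """Per-bin quality via the expected error rate (report default)."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_err = np.where(cov > 0, self.err_sum[: self.max_bin + 1] / cov, np.nan)
            return -10.0 * np.log10(mean_err)

    def base_fractions(self) -> np.ndarray:
        """(bins, 5) fractions of A,C,G,T,N per bin."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                cov[:, None] > 0,
                self.base_counts[: self.max_bin + 1] / cov[:, None],
                np.nan,
            )


@dataclass
class ReadSummaries:
    """Per-read histograms: length, GC percent, and mean quality in both
    averaging modes (1-Phred-unit bins, floor of the real-valued mean)."""

    length_hist: Counter = field(default_factory=Counter)
    gc_hist: np.ndarray = field(default_factory=lambda: np.zeros(101, dtype=np.int64))
    gc_undefined: int = 0
    q_hist_expected_error: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_PHRED + 1, dtype=np.int64)
    )
    q_hist_arithmetic: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_PHRED + 1, dtype=np.int64)
    )
    empty_reads: int = 0
    total_reads: int = 0

    def add(self, sequence: str, qualities: np.ndarray) -> None:
        self.total_reads += 1
        self.length_hist[len(sequence)] += 1
        gc = gc_percent(sequence)
        if gc is None:
            self.gc_undefined += 1
        else:
            self.gc_hist[min(100, int(gc))] += 1
        if len(qualities) == 0:
            self.empty_reads += 1
            return
        q_ee = read_mean_quality_expected_error(qualities)
        q_ar = read_mean_quality_arithmetic(qualities)
        self.q_hist_expected_error[min(MAX_PHRED, int(q_ee))] += 1
        self.q_hist_arithmetic[min(MAX_PHRED, int(q_ar))] += 1

    def reads_at_least(self, q: int, mode: str = "expected_error") -> int:
        """Number of reads whose mean quality is >= *q* in the given mode."""
        hist = (
            self.q_hist_expected_error
            if mode == "expected_error"
            else self.q_hist_arithmetic
        )
        return int(hist[q:].sum())


def accumulate(record, profile: PositionProfile, summaries: ReadSummaries) -> None:
    """Fold one read into the position profile and the read summaries."""
    profile.add(record.sequence, record.qualities)
    summaries.add(record.sequence, record.qualities)
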