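"""Run configuration: every tunable constant in one place."""
from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class QCConfig:
    """All tunable QC constants.

    The first five fields are the method's stated design constants;
    the remainder are gap-filling defaults documented in the methods
    note.  Fractions are expressed on [0, 1].
    """

    probe_len: int = 12            # adapter probe length, bases
    fingerprint_len: int = 16      # duplication fingerprint, bases
    sample_rate_denom: int = 8     # 1-in-N read sampling for fragment analysis
    fragment_store_cap: int = 5_000_000  # distinct fragments stored
    overrep_threshold: float = 0.001     # flag fragments above this occurrence

    fragment_len: int = 21         # sampled fragment window, bases (odd: no RC palindromes)
    kmer_size: int = 16            # contaminant index k
    sketch_capacity: int = 100_000  # duplication sketch capacity, fingerprints
    min_overlap: int = 10          # paired-end overlap, bases
    max_overlap_error: float = 0.10  # mismatch fraction allowed in the overlap
    min_identity: float = 0.80     # Smith-Waterman identity to accept a DB hit

    # local alignment scores: match, mismatch, gap open (first gap base), gap extend
    sw_match: int = 2
    sw_mismatch: int = -3
    sw_gap_open: int = -5
    sw_gap_extend: int = -2

    max_fragments_per_read: int = 8  # cap so ultra-long reads cannot dominate

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("probe_len", "fingerprint_len", "fragment_store_cap",
                     "fragment_len", "kmer_size", "sketch_capacity", "min_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.overrep_threshold < 1:
            raise ValueError("overrep_threshold must be in (0, 1)")
        if self.sample_rate_denom < 1:
            raise ValueError("sample_rate_denom must be >= 1")
        if not 0 <= self.max_overlap_error < 1:
            raise ValueError("max_overlap_error must be in [0, 1)")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)
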