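"""Single-end adapter detection by multi-pattern probe search.

Every read is scanned for a set of short (12 bp by default) probes taken
from known adapter/helper sequences, all patterns simultaneously, using
a bit-parallel shift-and automaton.  Matching is exact — N in the read
matches nothing — and only the leftmost occurrence per probe per read
contributes to the position histogram, so the adapter-content curves
count reads, not occurrences.
"""
from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

from .qc_metrics import PositionBinner

_PLATFORMS = ("illumina", "ont")


@dataclass(frozen=True)
class Probe:
    label: str
    probe_seq: str

    def validate(self, probe_len: int) -> None:
        if len(self.probe_seq) != probe_len:
            raise ValueError(
                f"probe {self.label!r} has length {len(self.probe_seq)}, "
                f"expected {probe_len}"
            )
        if any(c not in "ACGT" for c in self.probe_seq):
            raise ValueError(f"probe {self.label!r} contains non-ACGT characters")


class ShiftAndMatcher:
    """Bit-parallel shift-and over up to 64 equal-length probes.

    Probe *j* occupies bit block ``[j*L, (j+1)*L)`` of the scan state;
    one state update per read character matches all probes at once.
    Output is identical to a naive per-probe substring scan.
    """

    def __init__(self, probes: list[Probe], probe_len: int):
        if not 1 <= len(probes) <= 64:
            raise ValueError("need between 1 and 64 probes")
        for p in probes:
            p.validate(probe_len)
        self.probes = list(probes)
        self.probe_len = probe_len
        L = probe_len
        self._start_bits = 0
        self._accept_bits = 0
        masks = {c: 0 for c in "ACGT"}
        for j, p in enumerate(probes):
            self._start_bits |= 1 << (j * L)
            self._accept_bits |= 1 << (j * L + L - 1)
            for i, c in enumerate(p.probe_seq):
                masks[c] |= 1 << (j * L + i)
        self._masks = masks

    def scan(self, sequence: str) -> list[tuple[str, int]]:
        """Leftmost exact hit per probe: list of (label, 0-based start)."""
        L = self.probe_len
        masks = self._masks
        state = 0
        pending = self._accept_bits
        hits: list[tuple[str, int]] = []
        for pos, ch in enumerate(sequence):
            state = ((state << 1) | self._start_bits) & masks.get(ch, 0)
            found = state & pending
            while found:
                low = found & -found
                j = (low.bit_length() - 1) // L  # block index of the accept bit
                hits.append((self.probes[j].label, pos - L + 1))
                pending &= ~low
                found &= found - 1
            if not pending:
                break
        hits.sort(key=lambda h: h[1])
        return hits


def build_matcher(probes: list[Probe], probe_len: int = 12) -> ShiftAndMatcher:
    return ShiftAndMatcher(probes, probe_len)


def scan_read(matcher: ShiftAndMatcher, record) -> list[tuple[str, int]]:
    return matcher.scan(record.sequence)


def naive_scan(probes: list[Probe], sequence: str) -> list[tuple[str, int]]:
    """Reference implementation: per-probe ``str.find`` (leftmost hit).

    Kept as the behavioural contract for the bit-parallel matcher.
    """
    hits = []
    for p in probes:
        pos = sequence.find(p.probe_seq)
        if pos >= 0:
            hits.append((p.label, pos))
    hits.sort(key=lambda h: h[1])
    return hits


def load_probe_file(path_or_stream, probe_len: int = 12) -> list[Probe]:
    """Read a tab-separated (platform, label, sequence) probe file."""
    if hasattr(path_or_stream, "read"):
        rows = list(csv.reader(path_or_stream, delimiter="\t"))
    else:
        with open(path_or_stream, newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
    probes = []
    for row in rows:
        if not row or row[0].startswith("#"):
            continue
        platform, label, seq = row[0].strip(), row[1].strip(), row[2].strip().upper()
        probe = Probe(label=label, probe_seq=seq)
        probe.validate(probe_len)
        probes.append((platform, probe))
    return probes


def default_probe_set(platform_hint: str = "auto", probe_len: int = 12) -> list[Probe]:
    """Bundled probes: 12 bp windows of Illumina TruSeq/Nextera adapters
    and ONT ligation/rapid adapters; ``auto`` returns the union."""
    if platform_hint not in (*_PLATFORMS, "auto"):
        raise ValueError(
            f"unknown platform hint {platform_hint!r}; "
            f"expected one of {_PLATFORMS + ('auto',)}"
        )
    with resources.files("seqscope.data").joinpath("adapters.tsv").open() as fh:
        tagged = load_probe_file(fh, probe_len)
    if platform_hint == "auto":
        return [p for _, p in tagged]
    return [p for plat, p in tagged if plat == platform_hint]


class ProbeHits:
    """Aggregated probe-scan results across a read stream."""

    def __init__(self, probes: list[Probe]):
        self.labels = [p.label for p in probes]
        self.reads_with_hit = Counter()
        self.first_hit_bins: dict[str, Counter] = {lb: Counter() for lb in self.labels}
        self.binner = PositionBinner()
        self.total_reads = 0

    def add(self, hits: list[tuple[str, int]]) -> None:
        self.total_reads += 1
        for label, pos in hits:
            self.reads_with_hit[label] += 1
            bin_idx = int(self.binner.bins(pos + 1)[pos])
            self.first_hit_bins[label][bin_idx] += 1

    def hit_fraction(self, label: str) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.reads_with_hit[label] / self.total_reads
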