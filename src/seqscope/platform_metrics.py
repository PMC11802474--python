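"""Platform-specific statistics.

Illumina: per-tile quality (tile parsed from Casava 1.8+ read names).
ONT: per-channel activity, start-time series and translocation speed
(bases per second through the pore), from ``ch=``/``start_time=``/
``duration=`` comment tokens (FASTQ) or the equivalent uBAM tags.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .qc_metrics import read_mean_quality_expected_error


def parse_illumina_tile(name: str) -> int | None:
    """Tile number from a Casava 1.8+ read name
    (instrument:run:flowcell:lane:tile:x:y), else ``None``."""
    fields = name.split(":")
    if len(fields) < 7:
        return None
    tile = fields[4]
    return int(tile) if tile.isdigit() else None


@dataclass
class OntReadMeta:
    channel: int | None = None
    start_time: float | None = None  # seconds since epoch
    duration: float | None = None    # seconds

    @property
    def any_present(self) -> bool:
        return any(v is not None for v in (self.channel, self.start_time, self.duration))


def _parse_timestamp(value: str) -> float | None:
    try:
        return float(value)
    except ValueError:
        pass
    try:
        return datetime.fromisoformat(value.replace("Z", "+00:00")).timestamp()
    except ValueError:
        return None


def parse_ont_meta(record) -> tuple[OntReadMeta, list[str]]:
    """Extract ONT metadata tokens from a record's comment.

    Returns the metadata plus a list of warnings for malformed numeric
    values (the affected field is left absent).
    """
    meta = OntReadMeta()
    warnings: list[str] = []
    for token in record.comment.split():
        key, sep, value = token.partition("=")
        if not sep:
            continue
        if key == "ch":
            try:
                channel = int(value)
                if channel < 1:
                    raise ValueError
                meta.channel = channel
            except ValueError:
                warnings.append(f"read {record.name!r}: malformed channel {value!r}")
        elif key == "start_time":
            ts = _parse_timestamp(value)
            if ts is None:
                warnings.append(f"read {record.name!r}: malformed start_time {value!r}")
            else:
                meta.start_time = ts
        elif key == "duration":
            try:
                duration = float(value)
                if not duration > 0:
                    raise ValueError
                meta.duration = duration
            except ValueError:
                warnings.append(f"read {record.name!r}: malformed duration {value!r}")
    return meta, warnings


def translocation_speed(record, meta: OntReadMeta) -> float | None:
    """Bases per second, or ``None`` when no duration is available.

    When only a start time is present the speed is reported unavailable
    rather than inferred from inter-read gaps.
    """
    if meta.duration is None:
        return None
    return len(record.sequence) / meta.duration


class TileQuality:
    """Per-tile read counts and expected-error mean-quality sums."""

    def __init__(self) -> None:
        self.counts: Counter = Counter()
        self.q_sum: defaultdict = defaultdict(float)
        self.reads_with_tile = 0

    def add(self, record) -> None:
        tile = parse_illumina_tile(record.name)
        if tile is None:
            return
        self.reads_with_tile += 1
        self.counts[tile] += 1
        if len(record.qualities):
            self.q_sum[tile] += read_mean_quality_expected_error(record.qualities)

    def mean_quality(self) -> dict[int, float]:
        return {t: self.q_sum[t] / c for t, c in self.counts.items() if c}


class OntActivity:
    """Aggregated per-channel activity and translocation speeds."""

    #: time series resolution: run span / N bins, minimum bin width (s)
    TIME_BINS = 100
    MIN_BIN_SECONDS = 60.0

    def __init__(self) -> None:
        self.channel_reads: Counter = Counter()
        self.channel_bases: Counter = Counter()
        self.speeds: list[float] = []
        self.timed_speeds: list[tuple[float, float]] = []
        self.start_times: list[float] = []
        self.reads_with_channel = 0
        self.warnings: list[str] = []

    def add(self, record, meta: OntReadMeta) -> None:
        if meta.channel is not None:
            self.reads_with_channel += 1
            self.channel_reads[meta.channel] += 1
            self.channel_bases[meta.channel] += len(record.sequence)
        if meta.start_time is not None:
            self.start_times.append(meta.start_time)
        speed = translocation_speed(record, meta)
        if speed is not None:
            self.speeds.append(speed)
            if meta.start_time is not None:
                self.timed_speeds.append((meta.start_time, speed))

    def channel_activity(self) -> dict[int, tuple[int, int]]:
        """channel -> (reads, total bases); empty when no channel info."""
        return {
            ch: (self.channel_reads[ch], self.channel_bases[ch])
            for ch in sorted(self.channel_reads)
        }

    def speed_summary(self) -> dict | None:
        if not self.speeds:
            return None
        arr = np.asarray(self.speeds)
        return {
            "n": len(arr),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        }

    def speed_time_series(self) -> list[dict] | None:
        """Mean speed per time bin (run span / 100 bins, >= 1 minute)."""
        if len(self.timed_speeds) < 2:
            return None
        times = np.asarray([t for t, _ in self.timed_speeds])
        speeds = np.asarray([s for _, s in self.timed_speeds])
        t0, t1 = times.min(), times.max()
        width = max((t1 - t0) / self.TIME_BINS, self.MIN_BIN_SECONDS)
        bins = ((times - t0) / width).astype(int)
        out = []
        for b in np.unique(bins):
            sel = bins == b
            out.append(
                {
                    "t_start": float(t0 + b * width),
                    "n": int(sel.sum()),
                    "mean_speed": float(speeds[sel].mean()),
                }
            )
        return out


def channel_activity(metas) -> dict[int, tuple[int, int]]:
    """Standalone aggregation of (reads, bases) per channel from
    (record, meta) pairs or bare metas (bases then counted as 0)."""
    reads: Counter = Counter()
    bases: Counter = Counter()
    for item in metas:
        record, meta = item if isinstance(item, tuple) else (None, item)
        if meta.channel is None:
            continue
        reads[meta.channel] += 1
        bases[meta.channel] += len(record.sequence) if record is not None else 0
    return {ch: (reads[ch], bases[ch]) for ch in sorted(reads)}
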