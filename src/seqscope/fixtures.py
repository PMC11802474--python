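"""Deterministic synthetic-read libraries with known ground truth.

Every analysis module is exercised against libraries produced here: the
generator emits FASTQ (plain or gzip), paired FASTQ or uBAM together
with a manifest recording, per read, the true insert size, adapter
start, duplicate group, contaminant flag and ONT channel/duration —
so tests compare measured statistics against construction-time truth
rather than against other software.

Qualities follow a two-state Markov model (high ~Q35, low ~Q12 with
persistent runs), mimicking the within-read quality structure of real
data.  This is the regime where expected-error and arithmetic Phred
averaging diverge measurably: the arithmetic mean of a read that is
half Q35 / half Q12 sits near Q23.5 while its expected-error mean is
dominated by the low-quality bases and sits near Q15.

Duplicates are exact copies of earlier reads taken *before* error
injection, so with zero error rate duplicate fingerprints collide by
construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .records import ReadPair, SeqRecord, reverse_complement

#: full-length Illumina TruSeq read-1 adapter (probe set carries its 12 bp prefix)
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
#: ONT ligation-kit adapter Y-top segment
ONT_ADAPTER = "AATGTACTTCGTTCAGTTACGTATTGCT"

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i

_EPOCH = datetime(2023, 1, 1, tzinfo=timezone.utc).timestamp()


def _codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class LibrarySpec:
    """Parameters of one synthetic library.

    Defaults describe a plain error-free Illumina-like single-end
    library; switch on features (duplicates, spikes, pairing, ONT
    metadata) per test.
    """

    n_reads: int = 10_000
    read_len: int = 150
    #: (mean, sigma) of log read length — ONT-style length distribution
    length_lognormal: tuple[float, float] | None = None
    min_len: int = 30

    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0

    duplicate_fraction: float = 0.0
    adapter_seq: str = TRUSEQ_ADAPTER
    adapter_spike_fraction: float = 0.0
    contaminant_seq: str | None = None
    contaminant_fraction: float = 0.0

    error_rate: float = 0.0
    q_high: int = 35
    q_low: int = 12
    q_stay: float = 0.9  # per-state persistence of the quality Markov chain
    #: when set, every base gets this Phred score (skips the Markov model)
    constant_quality: int | None = None

    ont_meta: bool = False
    n_channels: int = 126
    speed_mean: float = 400.0  # translocation speed, bases/s
    speed_sd: float = 40.0

    illumina_names: bool = False
    tiles: tuple[int, ...] = (1101, 1102, 2101, 2102)

    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        for name in ("duplicate_fraction", "adapter_spike_fraction",
                     "contaminant_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.adapter_spike_fraction > 0 and len(self.adapter_seq) > self.read_len:
            raise ValueError("adapter longer than read length")
        if self.paired and self.duplicate_fraction > 0:
            raise ValueError("duplicates are only generated in single-end mode")
        if self.contaminant_fraction > 0 and self.contaminant_seq is None:
            raise ValueError("contaminant_fraction set but no contaminant_seq")


@dataclass
class Manifest:
    """Per-read ground truth for one generated library."""

    n_reads: int
    paired: bool
    insert_size: list[int | None] = field(default_factory=list)
    adapter_start: list[int | None] = field(default_factory=list)
    duplicate_group: list[int] = field(default_factory=list)  # group id = source index
    contaminant: list[bool] = field(default_factory=list)
    channel: list[int | None] = field(default_factory=list)
    duration: list[float | None] = field(default_factory=list)
    tile: list[int | None] = field(default_factory=list)

    @property
    def n_distinct(self) -> int:
        return len(set(self.duplicate_group))

    @property
    def true_remaining_fraction(self) -> float:
        return self.n_distinct / self.n_reads

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))

    def check(self) -> None:
        for name in ("insert_size", "adapter_start", "duplicate_group",
                     "contaminant", "channel", "duration", "tile"):
            if len(getattr(self, name)) != self.n_reads:
                raise AssertionError(f"manifest field {name} length mismatch")


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(fraction*n) True entries, at
    uniformly random positions (deterministic count, not Bernoulli)."""
    mask = np.zeros(n, dtype=bool)
    m = int(round(fraction * n))
    if m:
        mask[rng.choice(n, size=m, replace=False)] = True
    return mask


def _markov_qualities(
    rng: np.random.Generator, n: int, length: int, spec: LibrarySpec
) -> np.ndarray:
    """(n, length) Phred matrix from the two-state high/low model."""
    if length == 0:
        return np.zeros((n, 0), dtype=np.uint8)
    state = rng.random(n) < 0.5  # stationary start: half high, half low
    out = np.empty((n, length), dtype=np.uint8)
    out[:, 0] = np.where(state, spec.q_high, spec.q_low)
    for j in range(1, length):
        stay = rng.random(n) < spec.q_stay
        state = np.where(stay, state, ~state)
        out[:, j] = np.where(state, spec.q_high, spec.q_low)
    return out


def _inject_errors(
    rng: np.random.Generator, codes: np.ndarray, error_rate: float
) -> np.ndarray:
    if error_rate <= 0:
        return codes
    hit = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape)
    return np.where(hit, (codes + shift) % 4, codes).astype(np.uint8)


def _read_name(spec: LibrarySpec, rng: np.random.Generator, i: int,
               tile: int | None) -> str:
    if spec.illumina_names:
        x, y = int(rng.integers(1000, 30000)), int(rng.integers(1000, 30000))
        return f"SIM001:1:FCX:1:{tile}:{x}:{y}"
    return f"read{i}"


def _gen_codes(
    spec: LibrarySpec, rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray, Manifest]:
    """Pristine (pre-error) code arrays with spikes and duplicates applied."""
    n = spec.n_reads
    if spec.length_lognormal is not None:
        mu, sigma = spec.length_lognormal
        lengths = np.maximum(
            spec.min_len, rng.lognormal(mu, sigma, size=n).astype(int)
        )
    else:
        lengths = np.full(n, spec.read_len, dtype=int)

    if spec.length_lognormal is None:
        pristine = list(rng.integers(0, 4, size=(n, spec.read_len), dtype=np.uint8))
    else:
        pristine = [rng.integers(0, 4, size=int(L), dtype=np.uint8) for L in lengths]

    # spikes into the pristine pool (before duplication, so copies are exact)
    adapter_mask = _exact_subset(rng, n, spec.adapter_spike_fraction)
    adapter_codes = _str_to_codes(spec.adapter_seq)
    adapter_start: list[int | None] = [None] * n
    for i in np.flatnonzero(adapter_mask):
        L = len(pristine[i])
        if L < len(adapter_codes):
            continue
        a = L - len(adapter_codes)
        pristine[i][a:] = adapter_codes
        adapter_start[i] = a

    contam_mask = _exact_subset(rng, n, spec.contaminant_fraction)
    if spec.contaminant_seq is not None:
        contam_codes = _str_to_codes(spec.contaminant_seq)
        for i in np.flatnonzero(contam_mask):
            span = min(len(pristine[i]), len(contam_codes))
            pristine[i][:span] = contam_codes[:span]
    contaminant = contam_mask.tolist()

    # duplicates: exact copies of earlier reads, pre-error
    group = list(range(n))
    dup_mask = _exact_subset(rng, n, spec.duplicate_fraction)
    dup_mask[0] = False
    for i in np.flatnonzero(dup_mask):
        src = group[int(rng.integers(0, i))]  # chain to the original
        pristine[i] = pristine[src].copy()
        lengths[i] = len(pristine[i])
        group[i] = src
        adapter_start[i] = adapter_start[src]
        contaminant[i] = contaminant[src]

    manifest = Manifest(
        n_reads=n,
        paired=False,
        insert_size=[None] * n,
        adapter_start=adapter_start,
        duplicate_group=group,
        contaminant=contaminant,
        channel=[None] * n,
        duration=[None] * n,
        tile=[None] * n,
    )
    return pristine, lengths, manifest


def _apply_errors(
    spec: LibrarySpec, rng: np.random.Generator, pristine: list[np.ndarray]
) -> list[np.ndarray]:
    fixed = spec.length_lognormal is None and spec.duplicate_fraction == 0
    if spec.error_rate <= 0:
        return pristine
    if fixed:
        mat = _inject_errors(rng, np.stack(pristine), spec.error_rate)
        return list(mat)
    return [_inject_errors(rng, c, spec.error_rate) for c in pristine]


def generate_sequences(spec: LibrarySpec) -> tuple[list[str], Manifest]:
    """Sequences only (no qualities/names) — same bases, in the same
    order, as :func:`generate_single_end` with the same spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pristine, _, manifest = _gen_codes(spec, rng)
    final = _apply_errors(spec, rng, pristine)
    manifest.check()
    return [_codes_to_str(c) for c in final], manifest


def generate_single_end(spec: LibrarySpec) -> tuple[list[SeqRecord], Manifest]:
    """Single-end library (also covers ONT mode) plus its manifest."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reads
    pristine, lengths, manifest = _gen_codes(spec, rng)
    final = _apply_errors(spec, rng, pristine)

    # qualities: batched when all reads share a length
    if spec.constant_quality is not None:
        quals = [np.full(len(c), spec.constant_quality, dtype=np.uint8) for c in final]
    elif spec.length_lognormal is None:
        quals = list(_markov_qualities(rng, n, spec.read_len, spec))
    else:
        quals = [_markov_qualities(rng, 1, len(c), spec)[0] for c in final]

    # ONT metadata
    channels: list[int | None] = [None] * n
    durations: list[float | None] = [None] * n
    starts: list[float | None] = [None] * n
    if spec.ont_meta:
        ch = rng.integers(1, spec.n_channels + 1, size=n)
        speed = np.maximum(50.0, rng.normal(spec.speed_mean, spec.speed_sd, size=n))
        t = rng.uniform(0, 24 * 3600.0, size=n)
        channels = [int(c) for c in ch]
        durations = [float(len(c)) / s for c, s in zip(final, speed)]
        starts = [float(x) for x in t]
        manifest.channel = channels
        manifest.duration = durations

    if spec.illumina_names:
        manifest.tile = [int(t) for t in rng.choice(spec.tiles, size=n)]

    records = []
    for i in range(n):
        comment = ""
        if spec.ont_meta:
            iso = datetime.fromtimestamp(
                _EPOCH + starts[i], tz=timezone.utc
            ).strftime("%Y-%m-%dT%H:%M:%S.%f") + "Z"
            comment = f"ch={channels[i]} start_time={iso} duration={durations[i]:.4f}"
        records.append(
            SeqRecord(
                name=_read_name(spec, rng, i, manifest.tile[i]),
                comment=comment,
                sequence=_codes_to_str(final[i]),
                qualities=quals[i],
            )
        )
    manifest.check()
    return records, manifest


def generate_paired(spec: LibrarySpec) -> tuple[list[ReadPair], Manifest]:
    """Paired-end library: mates read the two ends of a normal-length
    insert; when the insert is shorter than the read length both mates
    read through into adapter and the remainder is random sequence."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, R = spec.n_reads, spec.read_len
    inserts = np.maximum(
        1, np.round(rng.normal(spec.insert_mean, spec.insert_sd, size=n)).astype(int)
    )
    adapter = spec.adapter_seq
    pairs = []
    adapter_start: list[int | None] = [None] * n
    for i in range(n):
        I = int(inserts[i])
        frag = rng.integers(0, 4, size=I).astype(np.uint8)
        frag_s = _codes_to_str(frag)
        if I >= R:
            s1, s2 = frag_s[:R], reverse_complement(frag_s)[:R]
        else:
            pad_len = max(0, R - I - len(adapter))
            pad1 = _codes_to_str(rng.integers(0, 4, size=pad_len).astype(np.uint8))
            pad2 = _codes_to_str(rng.integers(0, 4, size=pad_len).astype(np.uint8))
            s1 = (frag_s + adapter + pad1)[:R]
            s2 = (reverse_complement(frag_s) + adapter + pad2)[:R]
            adapter_start[i] = I
        c1 = _inject_errors(rng, _str_to_codes(s1), spec.error_rate)
        c2 = _inject_errors(rng, _str_to_codes(s2), spec.error_rate)
        q = _markov_qualities(rng, 2, R, spec)
        pairs.append(
            ReadPair(
                SeqRecord(f"pair{i}/1", "", _codes_to_str(c1), q[0]),
                SeqRecord(f"pair{i}/2", "", _codes_to_str(c2), q[1]),
            )
        )
    manifest = Manifest(
        n_reads=n,
        paired=True,
        insert_size=[int(x) for x in inserts],
        adapter_start=adapter_start,
        duplicate_group=list(range(n)),
        contaminant=[False] * n,
        channel=[None] * n,
        duration=[None] * n,
        tile=[None] * n,
    )
    manifest.check()
    return pairs, manifest


def generate_library(
    spec: LibrarySpec, outdir, fmt: str = "fastq"
) -> tuple[list[Path], Manifest]:
    """Generate a library and write it to *outdir*.

    ``fmt`` is one of ``fastq``, ``fastq.gz``, ``ubam`` (single-end) —
    paired specs always produce two FASTQ files.  Returns the written
    paths plus the manifest (also written as ``manifest.json``).
    Deterministic: the same spec (including seed) yields byte-identical
    files.
    """
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec.paired:
        pairs, manifest = generate_paired(spec)
        p1, p2 = outdir / "reads_R1.fastq", outdir / "reads_R2.fastq"
        io_formats.write_fastq((p.r1 for p in pairs), p1)
        io_formats.write_fastq((p.r2 for p in pairs), p2)
        paths = [p1, p2]
    else:
        records, manifest = generate_single_end(spec)
        if fmt == "ubam":
            path = outdir / "reads.bam"
            io_formats.write_ubam(records, path)
        elif fmt == "fastq.gz":
            path = outdir / "reads.fastq.gz"
            io_formats.write_fastq(records, path)
        elif fmt == "fastq":
            path = outdir / "reads.fastq"
            io_formats.write_fastq(records, path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths = [path]
    manifest.to_json(outdir / "manifest.json")
    return paths, manifest
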