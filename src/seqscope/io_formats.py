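"""Streaming readers: Sanger FASTQ (plain or gzip) and unaligned BAM.

Both inputs are normalised into :class:`~seqscope.records.SeqRecord`
streams so every downstream module is container-agnostic.  The FASTQ
reader is deliberately strict: modern sequencers emit 4-line records,
so wrapped (multi-line) FASTQ, offset-64 qualities and truncated
records all fail loudly instead of producing silently wrong statistics.
"""
from __future__ import annotations

import gzip
import io
import os
import warnings
from typing import BinaryIO, Iterable, Iterator

import numpy as np
import pysam

from .records import ReadPair, SeqRecord, canonical_name, normalise_sequence


class FastqFormatError(ValueError):
    pass


def _open_maybe_gzip(source, compressed: bool | None):
    if isinstance(source, (str, os.PathLike)):
        raw = open(source, "rb")
    else:
        raw = source
    if compressed is None:
        # sniff the gzip magic
        head = raw.peek(2) if hasattr(raw, "peek") else None
        if head is None:
            raw = io.BufferedReader(raw)
            head = raw.peek(2)
        compressed = head[:2] == b"\x1f\x8b"
    return gzip.open(raw, "rb") if compressed else raw


def read_fastq(source, compressed: bool | None = None) -> Iterator[SeqRecord]:
    """Yield records from a 4-line-per-record Sanger FASTQ stream.

    Parameters
    ----------
    source:
        Path or binary file object; gzip is detected from the magic
        bytes unless *compressed* is given explicitly.

    Raises
    ------
    FastqFormatError
        On truncated records, header/sequence/quality malformations,
        sequence/quality length mismatch, or quality characters outside
        the printable Sanger range (``!`` .. ``~``).
    """
    stream = _open_maybe_gzip(source, compressed)
    it = iter(stream)
    index = 0
    while True:
        try:
            header = next(it)
        except StopIteration:
            return
        lines = [header]
        for _ in range(3):
            try:
                lines.append(next(it))
            except StopIteration:
                raise FastqFormatError(
                    f"truncated FASTQ record at index {index}: "
                    f"fewer than 4 lines at end of file"
                ) from None
        header, seq, plus, qual = (ln.rstrip(b"\r\n") for ln in lines)
        if not header.startswith(b"@"):
            raise FastqFormatError(
                f"record {index}: header does not start with '@' "
                f"(multi-line FASTQ is not supported): {header[:40]!r}"
            )
        if not plus.startswith(b"+"):
            raise FastqFormatError(
                f"record {index}: separator line does not start with '+' "
                f"(multi-line FASTQ is not supported)"
            )
        name, _, comment = header[1:].decode("ascii").partition(" ")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"record {index} ({name!r}): sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        quals = np.frombuffer(qual, dtype=np.uint8).astype(np.int16) - 33
        if len(quals) and quals.min() < 0:
            raise FastqFormatError(
                f"record {index} ({name!r}): quality character below '!' "
                "(not Sanger offset-33 encoding)"
            )
        yield SeqRecord(
            name=name,
            comment=comment,
            sequence=normalise_sequence(seq.decode("ascii")),
            qualities=quals.astype(np.uint8),
        )
        index += 1


def write_fastq(records: Iterable[SeqRecord], sink) -> int:
    """Write *records* as 4-line FASTQ; returns the record count."""
    own = isinstance(sink, (str, os.PathLike))
    if own:
        opener = gzip.open if str(sink).endswith(".gz") else open
        sink = opener(sink, "wb")
    n = 0
    try:
        for rec in records:
            header = f"@{rec.name} {rec.comment}" if rec.comment else f"@{rec.name}"
            sink.write(
                (f"{header}\n{rec.sequence}\n+\n{rec.quality_string()}\n").encode("ascii")
            )
            n += 1
    finally:
        if own:
            sink.close()
    return n


# --- unaligned BAM ---------------------------------------------------------

#: uBAM tags carried into the SeqRecord comment as key=value tokens
_UBAM_TAG_TOKENS = (("ch", "ch"), ("st", "start_time"), ("du", "duration"))


def read_ubam(source) -> Iterator[SeqRecord]:
    """Yield records from an unaligned BAM (BGZF) file.

    Nibble-encoded sequences are decoded per the SAM specification;
    ambiguity codes other than N become N.  ONT-style tags (``ch``
    channel, ``st`` start time, ``du`` duration) are preserved in the
    comment as ``key=value`` tokens so the platform-metrics module can
    treat FASTQ and uBAM identically.  Records flagged as aligned are
    processed from SEQ/QUAL as stored, with a warning.
    """
    with pysam.AlignmentFile(str(source), "rb", check_sq=False) as bam:
        aligned_seen = False
        for i, rec in enumerate(bam.fetch(until_eof=True)):
            if not rec.is_unmapped and not aligned_seen:
                aligned_seen = True
                warnings.warn(
                    "reference-aligned records present in input treated as uBAM; "
                    "processing SEQ/QUAL as stored",
                    stacklevel=2,
                )
            if rec.query_qualities is None:
                raise ValueError(
                    f"uBAM record {i} ({rec.query_name!r}) has no quality values "
                    "(QUAL 0xFF)"
                )
            tokens = []
            for tag, key in _UBAM_TAG_TOKENS:
                if rec.has_tag(tag):
                    tokens.append(f"{key}={rec.get_tag(tag)}")
            yield SeqRecord(
                name=rec.query_name,
                comment=" ".join(tokens),
                sequence=normalise_sequence(rec.query_sequence),
                qualities=np.asarray(rec.query_qualities, dtype=np.uint8),
            )


def write_ubam(records: Iterable[SeqRecord], path, meta_from_comment: bool = True) -> int:
    """Write *records* as an unaligned BAM; ONT ``key=value`` comment
    tokens become ``ch``/``st``/``du`` tags when *meta_from_comment*."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}}
    n = 0
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec.name
            a.query_sequence = rec.sequence
            a.query_qualities = pysam.qualitystring_to_array(rec.quality_string())
            a.flag = 4  # unmapped
            if meta_from_comment and rec.comment:
                tags = dict(
                    tok.split("=", 1) for tok in rec.comment.split() if "=" in tok
                )
                if "ch" in tags:
                    a.set_tag("ch", int(tags["ch"]), "i")
                if "start_time" in tags:
                    a.set_tag("st", tags["start_time"], "Z")
                if "duration" in tags:
                    a.set_tag("du", float(tags["duration"]), "f")
            bam.write(a)
            n += 1
    return n


def pair_reads(
    stream1: Iterable[SeqRecord], stream2: Iterable[SeqRecord]
) -> Iterator[ReadPair]:
    """Zip two mate streams into :class:`ReadPair`, validating names."""
    it1, it2 = iter(stream1), iter(stream2)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            longer = "R2" if r1 is None else "R1"
            raise ValueError(
                f"unequal stream lengths: {longer} has extra records "
                f"starting at index {index}"
            )
        if canonical_name(r1.name) != canonical_name(r2.name):
            raise ValueError(
                f"mate name mismatch at record {index}: "
                f"{r1.name!r} vs {r2.name!r}"
            )
        yield ReadPair(r1, r2)
        index += 1


def sniff_format(path) -> str:
    """Return ``"bam"`` or ``"fastq"`` for *path*; raise on neither."""
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head == b"":  # empty file: a valid zero-record FASTQ
        return "fastq"
    if head[:2] == b"\x1f\x8b":  # gzip or BGZF: decompress the first bytes
        with gzip.open(path, "rb") as gz:
            inner = gz.read(4)
        return "bam" if inner == b"BAM\x01" else "fastq"
    if head == b"BAM\x01":
        return "bam"
    if head[:1] == b"@":
        return "fastq"
    raise ValueError(f"cannot detect input format of {path}")


def open_records(path) -> Iterator[SeqRecord]:
    """Dispatch to the FASTQ or uBAM reader based on file content."""
    fmt = sniff_format(path)
    return read_ubam(path) if fmt == "bam" else read_fastq(path)
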