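"""Core read containers shared by every analysis module.

A :class:`SeqRecord` is one sequencing read normalised to a five-letter
alphabet (``ACGTN``) with Sanger Phred qualities (0-93).  Both the FASTQ
and the uBAM reader produce these, so downstream modules never see
container-specific detail.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")
MAX_PHRED = 93  # '~' (126) - '!' (33): the printable Sanger range

_PAIR_SUFFIX = re.compile(r"/[12]$")

# uppercase + map every IUPAC ambiguity code except ACGT to N
_NORMALISE = bytes.maketrans(
    b"acgtnRYSWKMBDHVryswkmbdhvUu=",
    b"ACGTNNNNNNNNNNNNNNNNNNNNNTTN",
)


def normalise_sequence(seq: str) -> str:
    """Uppercase *seq* and collapse non-ACGT IUPAC codes to ``N``."""
    out = seq.encode("ascii").translate(_NORMALISE)
    bad = set(out.decode()) - VALID_BASES
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)!r}")
    return out.decode()


@dataclass
class SeqRecord:
    """One sequencing read.

    Parameters
    ----------
    name:
        Read identifier without the leading ``@``.
    comment:
        Header text after the first whitespace (may be empty).  ONT
        metadata (``ch=``, ``start_time=``, ``duration=``) lives here as
        ``key=value`` tokens.
    sequence:
        Bases over ``{A, C, G, T, N}``.
    qualities:
        Phred scores, one per base, each in ``[0, 93]``.
    """

    name: str
    comment: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.name!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and int(self.qualities.max()) > MAX_PHRED:
            raise ValueError(
                f"read {self.name!r}: quality above {MAX_PHRED} "
                "(is this offset-64 encoded?)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def quality_string(self) -> str:
        """Sanger (offset-33) encoding of the qualities."""
        return (self.qualities + 33).tobytes().decode("ascii")


def canonical_name(name: str) -> str:
    """Strip exactly one trailing ``/1`` or ``/2`` mate suffix."""
    return _PAIR_SUFFIX.sub("", name, count=1)


def _casava_mate(comment: str) -> str | None:
    # Casava 1.8+: comment leads with "1:N:0:..." / "2:N:0:..."
    if len(comment) >= 2 and comment[0] in "12" and comment[1] == ":":
        return comment[0]
    return None


@dataclass
class ReadPair:
    """A synchronised pair of mates.

    Mate identity is established by the canonical name (``/1``-``/2``
    suffix stripped); Casava-style pairing via the comment's leading
    ``1:``/``2:`` token is accepted when present.
    """

    r1: SeqRecord
    r2: SeqRecord

    def __post_init__(self) -> None:
        n1, n2 = canonical_name(self.r1.name), canonical_name(self.r2.name)
        if n1 != n2:
            raise ValueError(f"mate name mismatch: {self.r1.name!r} vs {self.r2.name!r}")
        m1, m2 = _casava_mate(self.r1.comment), _casava_mate(self.r2.comment)
        if m1 is not None and m2 is not None and (m1, m2) != ("1", "2"):
            raise ValueError(
                f"Casava mate tokens out of order for {self.r1.name!r}: {m1}/{m2}"
            )


_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")
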