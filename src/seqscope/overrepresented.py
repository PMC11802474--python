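"""Overrepresented-fragment detection and identification.

One in ``sample_rate_denom`` reads is cut into short fixed-length
fragments; the first ``fragment_store_cap`` distinct fragments are
stored and counted across the rest of the sample.  Fragments occurring
in more than ``overrep_threshold`` of the sampled reads are flagged and
identified against a contaminant database (UniVec-style FASTA) by
canonical k-mer candidate gathering followed by Smith-Waterman local
alignment.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .config import QCConfig
from .records import reverse_complement

# --- fragment sampling -----------------------------------------------------


def sample_fragments(record_or_seq, read_index: int, cfg: QCConfig) -> list[str]:
    """Fragments for one read, or ``[]`` when the read is not sampled.

    Sampled reads (``read_index % sample_rate_denom == 0``) are cut into
    non-overlapping ``fragment_len`` windows from the read start; long
    reads contribute at most ``max_fragments_per_read`` evenly spaced
    windows so they cannot dominate the table.  Windows containing N are
    skipped.
    """
    if read_index % cfg.sample_rate_denom != 0:
        return []
    seq = record_or_seq if isinstance(record_or_seq, str) else record_or_seq.sequence
    flen = cfg.fragment_len
    n_windows = len(seq) // flen
    if n_windows == 0:
        return []
    if n_windows > cfg.max_fragments_per_read:
        picks = np.unique(
            np.round(np.linspace(0, n_windows - 1, cfg.max_fragments_per_read)).astype(int)
        )
    else:
        picks = range(n_windows)
    out = []
    for w in picks:
        frag = seq[w * flen : (w + 1) * flen]
        if "N" not in frag:
            out.append(frag)
    return out


class FragmentTable:
    """Sampled-fragment counts with a distinct-key cap."""

    def __init__(self, cfg: QCConfig):
        self.cfg = cfg
        self.counts: dict[str, int] = {}
        self.distinct_cap = cfg.fragment_store_cap
        self.sampled_reads = 0
        self.table_saturated = False

    def update(self, fragments: list[str]) -> None:
        counts = self.counts
        for frag in fragments:
            if frag in counts:
                counts[frag] += 1
            elif len(counts) < self.distinct_cap:
                counts[frag] = 1
            else:
                self.table_saturated = True

    def add_read(self, record_or_seq, read_index: int) -> None:
        if read_index % self.cfg.sample_rate_denom == 0:
            self.sampled_reads += 1
            self.update(sample_fragments(record_or_seq, read_index, self.cfg))


def table_update(table: FragmentTable, fragments: list[str]) -> FragmentTable:
    table.update(fragments)
    return table


def flag_overrepresented(
    table: FragmentTable, cfg: QCConfig
) -> list[tuple[str, int, float]]:
    """Fragments whose occurrence fraction among sampled reads strictly
    exceeds the threshold; sorted by count descending, ties lexicographic."""
    if table.sampled_reads == 0:
        raise ValueError("no sampled reads: cannot compute occurrence fractions")
    n = table.sampled_reads
    flagged = [
        (frag, count, count / n)
        for frag, count in table.counts.items()
        if count / n > cfg.overrep_threshold
    ]
    flagged.sort(key=lambda t: (-t[1], t[0]))
    return flagged


# --- contaminant database --------------------------------------------------


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class ContaminantDB:
    entries: list[tuple[str, str, str]]  # (id, description, sequence)
    kmer_index: dict[str, list[tuple[int, int]]]  # canonical k-mer -> (entry, pos)
    kmer_size: int


def _iter_fasta(source):
    """(id, description, sequence) triples from a FASTA path or stream."""
    own = False
    if hasattr(source, "read"):
        fh = source
    else:
        fh = open(source)
        own = True
    try:
        name, desc, chunks = None, "", []
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, desc, "".join(chunks)
                head = line[1:].split(None, 1)
                name = head[0]
                desc = head[1] if len(head) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line.upper())
        if name is not None:
            yield name, desc, "".join(chunks)
    finally:
        if own:
            fh.close()


def build_contaminant_index(fasta, cfg: QCConfig) -> ContaminantDB:
    """Index every ACGT-only window of length ``kmer_size`` in every
    entry under its canonical form.  Non-ACGT characters break windows."""
    k = cfg.kmer_size
    entries = list(_iter_fasta(fasta))
    if not entries:
        raise ValueError("contaminant FASTA contains no entries")
    index: dict[str, list[tuple[int, int]]] = {}
    for ei, (_, _, seq) in enumerate(entries):
        for pos in range(len(seq) - k + 1):
            window = seq[pos : pos + k]
            if any(c not in "ACGT" for c in window):
                continue
            index.setdefault(canonical_kmer(window), []).append((ei, pos))
    return ContaminantDB(entries=entries, kmer_index=index, kmer_size=k)


def bundled_contaminant_db(cfg: QCConfig) -> ContaminantDB:
    """The bundled mini-database: synthetic vector entries plus known
    Illumina/ONT adapter sequences (UniVec-compatible headers)."""
    with resources.files("seqscope.data").joinpath("contaminants.fasta").open() as fh:
        return build_contaminant_index(fh, cfg)


# --- Smith-Waterman local alignment ----------------------------------------


@dataclass
class AlignmentResult:
    score: int
    identity: float
    target_id: str
    target_span: tuple[int, int]  # 0-based half-open
    query_span: tuple[int, int]
    strand: str = "+"


def smith_waterman(
    query: str,
    target: str,
    scores: tuple[int, int, int, int] = (2, -3, -5, -2),
) -> AlignmentResult | None:
    """Affine-gap local alignment (Gotoh).

    ``scores`` is (match, mismatch, gap_open, gap_extend); a gap of
    length k scores ``gap_open + (k-1)*gap_extend``.  The best cell is
    the first maximal one in row-major order; traceback prefers
    diagonal over up (gap in target) over left (gap in query).  Returns
    ``None`` when no cell scores positive.
    """
    if not query or not target:
        raise ValueError("smith_waterman requires non-empty sequences")
    match, mismatch, gap_open, gap_extend = scores
    m, n = len(query), len(target)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (left)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in target (up)
    for i in range(1, m + 1):
        qc = query[i - 1]
        Hi, Hp, Ei, Fi, Fp = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] + gap_open, Ei[j - 1] + gap_extend)
            Fi[j] = max(Hp[j] + gap_open, Fp[j] + gap_extend)
            diag = Hp[j - 1] + (match if qc == target[j - 1] else mismatch)
            Hi[j] = max(0, diag, Ei[j], Fi[j])
    best = int(H.max())
    if best <= 0:
        return None
    bi, bj = np.unravel_index(int(np.argmax(H)), H.shape)  # first max, row-major

    # traceback with the documented tie preference
    i, j, state = int(bi), int(bj), "H"
    matches = columns = 0
    end_i, end_j = i, j
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + (match if query[i - 1] == target[j - 1] else mismatch)
            if i > 0 and j > 0 and H[i, j] == diag:
                matches += query[i - 1] == target[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # up: query char against gap
            columns += 1
            from_open = H[i - 1, j] + gap_open
            i, state = i - 1, ("H" if F[i, j] == from_open else "F")
        else:  # E, left: target char against gap
            columns += 1
            from_open = H[i, j - 1] + gap_open
            j, state = j - 1, ("H" if E[i, j] == from_open else "E")
    return AlignmentResult(
        score=best,
        identity=matches / columns if columns else 0.0,
        target_id="",
        target_span=(j, end_j),
        query_span=(i, end_i),
    )


def identify_fragment(
    fragment: str, db: ContaminantDB, cfg: QCConfig
) -> AlignmentResult | None:
    """Best database hit for *fragment*, or ``None``.

    Candidates are entries sharing at least one canonical k-mer with the
    fragment (both strands, implicitly, via canonicalisation); each is
    scored by Smith-Waterman of the fragment — forward and reverse
    complement — against the entry.  The best hit is returned when its
    identity reaches ``min_identity``.
    """
    k = cfg.kmer_size
    if len(fragment) < k:
        raise ValueError(f"fragment shorter than k-mer size {k}")
    candidates: set[int] = set()
    for pos in range(len(fragment) - k + 1):
        window = fragment[pos : pos + k]
        if "N" in window:
            continue
        for ei, _ in db.kmer_index.get(canonical_kmer(window), ()):
            candidates.add(ei)
    scores = (cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap_open, cfg.sw_gap_extend)
    best: AlignmentResult | None = None
    for ei in sorted(candidates):
        entry_id, _, entry_seq = db.entries[ei]
        for strand, query in (("+", fragment), ("-", reverse_complement(fragment))):
            res = smith_waterman(query, entry_seq, scores)
            if res is None:
                continue
            res.target_id = entry_id
            res.strand = strand
            if best is None or res.score > best.score:
                best = res
    if best is not None and best.identity >= cfg.min_identity:
        return best
    return None
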