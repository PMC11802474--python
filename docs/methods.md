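# Methods

This note documents the models, estimators and numerical choices behind
`seqscope`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know about.

## Read model and input handling

A read is a sequence over `{A,C,G,T,N}` with Sanger Phred scores
(0–93). Lowercase bases are uppercased and every IUPAC ambiguity code
other than `ACGT` becomes `N` on input, so downstream modules assume a
five-letter alphabet. Quality values above 93 are rejected rather than
clamped: offset-64 (old Solexa) input fails loudly instead of producing
silently shifted statistics. Multi-line (wrapped) FASTQ is rejected —
modern sequencers emit 4-line records, and accepting wrapped records
would make truncation detection ambiguous. uBAM records flagged as
aligned are processed from SEQ/QUAL as stored, with a warning; records
without quality values (QUAL 0xFF) are an error because every
downstream statistic needs them.

Paired-end mate identity accepts the two dominant dialects: a trailing
`/1`–`/2` name suffix, or Casava-style `1:`/`2:` comment tokens.

## Quality averaging

Per-read quality is `−10·log10(mean error probability)`; the arithmetic
Phred mean is computed alongside as a comparison mode. By Jensen's
inequality arithmetic ≥ expected-error always, with equality only for
constant quality; the gap grows with within-read quality dispersion.
Per-read histograms bin at the floor of the real-valued mean
(bins 0–93), matching "reads ≥ Q15"-style reporting. Empty reads are
counted in a separate bin so histogram totals always equal reads
processed.

Per-position quality is aggregated both as mean Phred and as
Phred-of-mean-error; the report shows the expected-error version by
default. Positions are exact per base up to 500; beyond that they fall
into bins whose width grows ×1.1 per bin (integer-rounded), bounding
profile memory at a few hundred bins even for megabase nanopore reads.
The binning scheme is this package's own choice.

## Adapter probes and paired-end overlap

Probe matching is exact (no mismatches) over 12 bp probes — short
enough to tolerate adapter truncation at read ends, long enough that a
random hit occurs in ~6·10⁻⁸ of positions. The matcher is a
bit-parallel shift-and automaton over up to 64 probes (one bit block
per probe); its contract is output-equivalence with a naive per-probe
scan, which the tests enforce exhaustively over a two-letter alphabet
and on randomized reads. `N` matches nothing. Only the leftmost hit per
probe per read enters the position histogram, so adapter-content curves
count reads, not occurrences. Probes are searched as given;
reverse-complement variants are separate labelled entries, keeping
strandedness explicit.

Paired-end overlap enumerates every ungapped offset of R1 against
RC(R2) in one vectorised pass. An offset qualifies with overlap ≥ 10
bases and mismatch fraction ≤ 0.10 (both configurable); among
qualifying offsets the most matching bases win, ties toward the
smallest insert. Mismatches are plain counts — quality-aware weighting
was considered and rejected to keep the contract simple and
deterministic. Indels inside the overlap are not modelled; true
insert-size errors from indel-bearing overlaps show up as either an
off-by-k insert or an undetermined pair. With 50 bp random pairs the
chance-qualification rate measured by simulation is ~0.02 %.

## Duplication estimation

The fingerprint takes the 8-mer starting at offset
`f = min(64, max(0, L−16))` and the 8-mer ending `f` bases before the
read end (whole read, left-padded with `A`, when L < 16; `N` maps to
`A`). Skipping up to 64 leading/trailing bases avoids counting
adapter/barcode-bearing read ends as "identical". For reads between 80
and 144 bases the two windows can cross; this is deterministic and
harmless since only fingerprint identity matters. Identical reads
always collide; distinct random reads collide with probability
~2⁻³²·pairs (measured < 1 % at 10⁴ reads).

The sketch tracks a fingerprint iff the low *d* bits of its SplitMix64
hash are zero. When the tracked set exceeds its capacity (default
100,000), *d* increments and failing entries are evicted with their
counts discarded (no rescaling): because the criterion depends only on
the fingerprint, every surviving count is exact, and scaling surviving
entries by 2^d gives an unbiased estimate of distinct counts and of the
multiplicity histogram. The histogram pools multiplicities ≥ 16 into
one bucket and is labelled approximate once eviction has occurred.
SplitMix64 is fixed and unsalted, so results are identical across runs
and platforms. Below capacity the estimator degenerates to exact
counting — tests assert oracle equality there, and mean-unbiasedness
within 1 percentage point (20 streams of 10⁵ reads, capacity 10³) under
eviction.

## Overrepresented fragments

Sampling is deterministic: reads at index ≡ 0 (mod 8) are cut into
non-overlapping 21 bp windows (odd length: a fragment can never equal
its own reverse complement), at most 8 evenly spaced windows per read
so ultra-long reads cannot dominate the table; windows containing `N`
are skipped. The table stores the first 5 million *distinct* fragments
(a distinct-key cap; existing keys keep counting after saturation). The
flagging threshold is strict: fraction > 0.1 % of *sampled reads* —
reads, not fragment instances, are the denominator, so a fragment
present once per read at spike fraction *f* is flagged iff f > 0.001
regardless of read length.

Identification gathers candidate database entries sharing at least one
canonical 16-mer with the fragment (canonical = lexicographic min of
k-mer and reverse complement, making the index strand-insensitive),
then scores each candidate with Smith–Waterman (match +2, mismatch −3,
gap open −5, gap extend −2 — common vector-screening scores; a gap of
length k costs 5 + 2(k−1)). The fragment is aligned forward and
reverse-complemented; the best hit is reported when identity
(matches / alignment columns) ≥ 0.80. Traceback tie-breaking is fixed:
best cell is the first maximum in row-major order; diagonal is
preferred over up over left. With 21 bp fragments and k = 16 there are
6 k-mer windows, so one mismatch still leaves sharing windows for
candidate gathering.

## Platform metrics

Tiles come from field 5 of colon-delimited Casava 1.8+ names;
unparseable names are skipped, never fatal. ONT metadata comes from
`ch=`, `start_time=`, `duration=` comment tokens, or `ch`/`st`/`du`
uBAM tags mapped to the same tokens so FASTQ and uBAM behave
identically. Translocation speed is length/duration; when only a start
time is present the speed is reported unavailable rather than inferred
from inter-read gaps. Time series use run-span/100 bins with a 1-minute
minimum. Report sections render only for the platform whose metadata is
actually present.

## Synthetic libraries (ground truth for every test)

The generator emits FASTQ/gzip/uBAM plus a manifest of per-read truth
(insert size, adapter start, duplicate group, contaminant flag,
channel/duration). Design points:

- **Quality model**: per-base quality follows a two-state Markov chain,
  high = Q35, low = Q12, stay-probability 0.9 per state (expected run
  length 10 bases, stationary split 50/50). This mimics the within-read
  quality structure of real data and is the regime where the two
  averaging modes diverge: a 150 bp read has ~17 effective independent
  quality segments, giving mean arithmetic quality ≈ 23.5 with enough
  read-to-read spread that most reads exceed Q20 arithmetically while
  almost none do on the expected-error scale.
- Duplicates are exact copies of earlier reads *before* error
  injection, so fingerprint collisions are guaranteed at error rate 0
  and the manifest's distinct-read count is exact truth.
- Spikes (adapter, contaminant) are applied to the pristine pool with
  an exact count (round(f·n) reads), not Bernoulli draws, so realized
  fractions equal requested ones.
- Paired mode draws insert sizes from a truncated normal; mates read
  through into adapter (then random padding) whenever insert < read
  length, giving exact adapter-position truth.
- Everything derives from one `numpy` PCG64 stream per spec seed; the
  same spec yields byte-identical files.

What the generator does **not** emulate: realistic ONT error profiles
(homopolymer indels), quality-dependent base errors, optical/tile
duplication structure, GC-coverage bias, or real adapter chemistry
beyond literal sequence insertion. Passing tests therefore demonstrate
the estimators' correctness under their stated models, not performance
on any particular instrument's artefacts.

## Problem sizes and numerical choices

Test and acceptance runs use 10³–10⁵-read libraries — large enough that
the stochastic assertions sit several standard deviations inside their
bounds (e.g. duplication unbiasedness uses 20 × 10⁵-read streams;
overlap false positives use 10⁴ random pairs; matcher equivalence is
exhaustive over all ~2·10⁶ two-letter reads up to 20 bp). Estimator
tolerances are stated per test next to the variance reasoning. Ties and
degenerate inputs are all pinned: empty reads, all-`N` reads (GC
undefined bin), empty files (valid zero-read reports), zero-quality
bases, and saturated tables each have dedicated tests.

## Known limitations

- Gapped overlaps and quality-aware overlap scoring are out of scope;
  insert sizes from indel-rich pairs may be off or undetermined.
- The multiplicity histogram after eviction is an estimate, not a
  count; the report flags this.
- The bundled contaminant database is a small fixture (synthetic vector
  segments plus real adapter sequences); screening against the full
  NCBI UniVec requires passing it via `--contaminants`.
- Threading (`--threads`) is accepted for interface compatibility but
  currently processes on one thread; results never depend on it.
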