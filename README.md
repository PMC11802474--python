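# seqscope

Streaming quality control for short- and long-read sequencing data.

`seqscope` computes sequencing QC statistics from Sanger FASTQ (plain or
gzip, single- or paired-end) and unaligned BAM (uBAM) in a single pass,
for both Illumina-style short reads and ONT-style long reads. It is
aimed at sequencing-core and pipeline engineers who need one QC tool
for both technologies, covering analyses that ONT-oriented tools
typically lack (adapter search, overrepresented sequences, duplication)
while reporting read quality the statistically correct way.

## What it computes

**Per-read quality via the expected error rate.** The mean quality of a
read with per-base Phred scores *q₁…q_L* is

    Q_read = −10 · log₁₀( (1/L) Σᵢ 10^(−qᵢ/10) )

i.e. Phred scores are converted to error probabilities, averaged, and
converted back. The naive alternative — arithmetically averaging the
Phred scores — is never smaller (Jensen's inequality) and systematically
overestimates read quality whenever quality varies within the read.
`seqscope` reports the expected-error value by default and keeps the
arithmetic mode as an explicit comparison.

**Adapter content.** Every read is scanned for 12 bp probes taken from
known Illumina and ONT adapters, all probes simultaneously, with a
bit-parallel shift-and matcher (exact matching; output identical to a
naive scan). For paired-end data, adapters and insert sizes come from
read overlap instead: R1 is aligned ungapped against the
reverse-complemented R2 at every offset; an overlap of ≥ 10 bases with
≤ 10 % mismatches determines the insert size, and an insert shorter
than the read length pins the read-through adapter start exactly.

**Duplication.** Each read is reduced to a 16 bp fingerprint (two
8-mers from fixed offsets, 2 bits/base). Fingerprints are counted in a
sketch that subsamples by hash value: at depth *d* a fingerprint is
tracked iff the low *d* bits of its SplitMix64 hash are zero, and the
depth grows when the sketch outgrows its capacity. Surviving counts are
exact, so multiplying by 2^d gives an accurate, memory-bounded estimate
of the duplication profile — unlike count-the-first-N-reads schemes,
which overestimate unique reads.

**Overrepresented fragments.** One read in eight is cut into 21 bp
fragments; the first 5 million distinct fragments are stored and
counted across the rest of the sample. Fragments exceeding 0.1 % of
sampled reads are identified against a contaminant database
(UniVec-style FASTA; a small fixture database is bundled) by canonical
k-mer candidate gathering followed by Smith–Waterman alignment
(+2/−3 match/mismatch, −5/−2 affine gaps).

**Platform metrics.** Illumina per-tile quality (from Casava read
names) and ONT per-channel activity plus translocation speed
(bases/second, from `ch=`/`start_time=`/`duration=` tokens or the
equivalent uBAM tags).

## Worked example

```python
from seqscope.fixtures import LibrarySpec, generate_library
from seqscope.report import run_qc, write_json, write_html
from seqscope.config import QCConfig

# a synthetic 10,000-read library with the two-state quality model
(path,), manifest = generate_library(LibrarySpec(n_reads=10_000, seed=1), "demo")
report = run_qc([path], QCConfig())
s = report.summary
print(s["total_reads"], s["reads_q20_arithmetic"], s["reads_q20_expected_error"])
```

prints

```
10000 8865 11
```

10,000 reads whose arithmetic-mean quality is ≈ Q23.5: the arithmetic
mode calls 8,865 of them "Q ≥ 20", while the expected-error mode —
dominated by each read's low-quality stretches — calls only 11. The
same object serialises with `write_json(report, "seqscope.json")`
(stable schema, MultiQC-consumable) and
`write_html(report, "seqscope.html")` (single self-contained file).

Or from the shell:

```bash
seqscope demo/reads.fastq --outdir qc_out
seqscope R1.fastq.gz R2.fastq.gz --outdir qc_out        # paired-end
seqscope nanopore.bam --contaminants UniVec.fasta       # uBAM + full UniVec
```

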