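# seqscope bundled adapter probes, v1
# columns: platform <TAB> label <TAB> 12 bp probe sequence
# Illumina probes are 12 bp prefixes of the published adapter sequences;
# (RC) entries are reverse complements searched as separate labels.
illumina	Illumina TruSeq Adapter	AGATCGGAAGAG
illumina	Illumina TruSeq Adapter (RC)	CTCTTCCGATCT
illumina	Illumina Nextera Adapter	CTGTCTCTTATA
illumina	Illumina Nextera Adapter (RC)	TATAAGAGACAG
illumina	Illumina Small RNA 3' Adapter	TGGAATTCTCGG
ont	ONT Ligation Kit Adapter	TACTTCGTTCAG
ont	ONT Ligation Kit Adapter (RC)	CTGAACGAAGTA
ont	ONT Rapid Adapter	GTTTTCGCATTT
ont	ONT Rapid Adapter (RC)	AAATGCGAAAAC
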