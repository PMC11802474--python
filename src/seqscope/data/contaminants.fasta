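>uvsynth001.1 synthetic cloning-vector segment 1 (generated fixture, not a real UniVec entry)
TCATGTAAAGATAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATGGAATAACCCCAGCCC
AGGGCAAGGCAGCACTCCGTAAGCGACGGAGCAGTCCA
>uvsynth002.1 synthetic cloning-vector segment 2 (generated fixture, not a real UniVec entry)
CCATTTATTGGCACGCGGTCTCCCTTCCGATGACACCAACGGCTCCGCCCATCGGGTTTATTGGGTTTTG
TGGAAGCTGTCGATCACCAGCCTAGGCAAGGGTAAGGGTGCTA
>uvsynth003.1 synthetic cloning-vector segment 3 (generated fixture, not a real UniVec entry)
ATGCAGGACTGCGAGGAACAAACGTTCTCTGCGACTAGGAGGTTGACCGTGGCGAGATCCCGTGAAGATA
AACCTAGAAGATTGGATCATCAG
>uvsynth004.1 synthetic cloning-vector segment 4 (generated fixture, not a real UniVec entry)
GTGAACATGACCAGGCCCTATCGAGTTGTTATGGGTTCTAGATTTACAGCGCTGGATGACTATGCGACTC
TCCCGATTCTGGTTATCAAGGTATCGCGTTATTCGCATGCT
>uvsynth005.1 synthetic cloning-vector segment 5 (generated fixture, not a real UniVec entry)
TCGCCAGATGAAGGTATTTAATTCGCTAAATGTAGTACTGTCGAGAGAGAGAAAACCATGGGTGGTTACC
CCTGCAAGTGGAAAAACTGACACCCACTTGGCAAGTTTGTGTAGACGCCAGATGGTACCTGTATATCCTG
TGCCCCCGGGACAGGCCAGGATTTAATTGATTT
>uvsynth006.1 synthetic cloning-vector segment 6 (generated fixture, not a real UniVec entry)
AGCTGGAGGAAACCTTTACGCAGTTGTAGACGATCCAGATCTTGTCACAGACTATTTTAGTAGAGAAGTA
ACTGGTCGAGGACAGGATTGGGTAGCGTT
>uvsynth007.1 synthetic cloning-vector segment 7 (generated fixture, not a real UniVec entry)
GAAAAGAGCGGTATGTCTGTCCTTTACGGGGTGGGACCTCCACGGACACTCCTTTTTGTACCTTAGGACA
ACGCATTTTTATACAATCCGCATACTTATCCATGATGGGTCATAACGTCACGCGTTCGGGTCATCAATCC
AG
>uvsynth008.1 synthetic cloning-vector segment 8 (generated fixture, not a real UniVec entry)
CATTGGCCATAATTCGCTGAGTCCCATTAAGGGGGAAGAACTTTCCACTTTCAGTTCGGCACATGGCACG
CCCCTTGAGGAATCCTTACTTGACTCAACTTGCGGCTTAGAGCGTAAGCGTCGATGGTAGCGAGTCTTAG
CATTTGATATTTGCGCTAGGC
>uvsynth009.1 synthetic cloning-vector segment 9 (generated fixture, not a real UniVec entry)
GGACTTAACCGCCCCGCATTGTCTTTAGTTTACGTTATTTATCAACGCGTCCTGATCCTACGAGACTCCC
GAATTCCCCCTGATCCCGGTTTCACTAAGTTAAAGGCTGCAACGACTAGGAGACAATCAAGGGTTCCAAG
TCTTCCTTGTCC
>uvsynth010.1 synthetic cloning-vector segment 10 (generated fixture, not a real UniVec entry)
ATGGCAGGGAATAATCGTATCGTGTACAACCCAGAGCCTGAAAGCAGTGCCATCTTGGCAATTAGCGAAT
GTGTTTGGGCAGTCACAGCAATGCCTACCGTCGCT
>uvsynth011.1 synthetic cloning-vector segment 11 (generated fixture, not a real UniVec entry)
ACGTTATTGGTATTCCACCGACAGTGCGCCTGTCAAGCGCATGCACCCATAATGGAGTATACCTTACCGG
TTACTAACTGCCAAATGTTTCCCTAAAGCGGCGTTTAGCCTATGGTGAACTAGCGGGCCAAAATGATGTC
TGTGGGGGTCTAAAAAGAGTAGCGATAT
>uvsynth012.1 synthetic cloning-vector segment 12 (generated fixture, not a real UniVec entry)
GATATCCGCCTTGTGTTCCAAACCCTTGAACAGTTCGACCGTGCTAACAGGTTACCACCCCATCACATAA
TTCGTTCTGGCAAGCACCACATTTGCGCTGACGTCAGGGTGATGAGAACTAGAGCGCTGACG
>uvsynth013.1 synthetic cloning-vector segment 13 (generated fixture, not a real UniVec entry)
GGCGAAGTGGGAACTTGCCACTGGCCGCGCGGGGGCGAGGAAAGGACTGCCTACGTCTCAGGTAGGGATC
CGACTTTAAGGTTAGATTCGGCCAATGGCCGACACGGCTTTCCGACGAATTGCTTAAGGGACAACACTTG
GAC
>uvsynth014.1 synthetic cloning-vector segment 14 (generated fixture, not a real UniVec entry)
AGGGCTTACCTAAGTTATCGTTCAAAGAGCATAGACATTGAGCTTGCTACGAGCCGTCTGAGTGCGATAA
AGGTTGTGCCCTTCTGAGAGCAGATTTTGCATTAATGCGTTCTTAGTATATACCTCCT
>illumina_truseq_r1 Illumina TruSeq adapter, read 1
AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
>illumina_truseq_r2 Illumina TruSeq adapter, read 2
AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA
>illumina_nextera Illumina Nextera transposase sequence
CTGTCTCTTATACACATCTCCGAGCCCACGAGAC
>ont_ligation_adapter ONT ligation kit adapter Y-top
AATGTACTTCGTTCAGTTACGTATTGCT
>ont_rapid_adapter ONT rapid adapter
GTTTTCGCATTTATCGTGAAACGCTTTCGCGTTTTTCGTGCGCCGCTTCA
>ont_barcode01 ONT native barcode 01
CACAAAGACACCGACAACTTTCTT
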