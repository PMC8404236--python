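>fxn_intron1_flank_synthetic synthetic stand-in for the non-GAA FXN intron-1 amplicon flank (no GAA run >= 4 triplets); override with --flank for a real locus sequence
CCTACCGAAGAGAAATTAATGCTTAGACCGTGGATCGATACAGAAACTGCCGCCTAAATGACTAACCGTGAACGGTAATG
GGCTAAAGCGCTTACTCTTAGAGCTAGGCCTAGTCAGTTCTCTACGCTAACCACTTGGGGCGCACGGCATCCGGACACTT
GAGTCGAACTGACACGGCCTTCCAAAGGCAGGTATCCGAAGTAAGCAAAGATCCGTTGAGAGTACATGGATTGAGTATCT
CTGAAAACACGTAGTTGGCCGGGGAGGCAGCTGGACTCTACAGATAGTGAAGTACGGGGTTAAAGTGACAGGGCACGCGT
AGCATCCGGCGTCAGTGTGAACGCTAGCAGCGCAAGGGAGCGGCCACCGCACCGAGAAGGCGCTCTTGAATGTCAATGTA
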