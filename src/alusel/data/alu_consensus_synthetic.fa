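>alu_consensus_synthetic synthetic 300-nt Alu-like consensus (not a Repbase sequence)
GCTGCTGGCGACAATAGCGGTCGATAGCCACGATAAATCTAAGGAGTGCCGGCCTAATCT
CACACCCCCTTCTTCTCGCGCTGGATTGAAATGAGTCTGGCGCATGCCGCGACATCAACT
GGCTCCACATACTCGTTATTTGACTGACTGTCGCTCGCGCCCTCCTTAACATGGGCACTG
GTTGGCTCCGCGACGGCAGCAATAGCGACTTGAGACTGACAACGGGGTCACAGTACAGCG
TGAACAGGTCAAGCTAAGGTTCTCCACAAACAACACAAGGGACCGGGCGCATTGTTAAGG
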