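pair_id,forward,reverse,junction,junction_locus,amplicon_len,fwd_tm,rev_tm,fwd_gc,rev_gc,amplicon_tm,pair_penalty,final_score,detected_transcripts,non_target_isoforms,off_target_genes,genomic_products,unproductive_hits,flagged
P007,CGGTGTGTGAACCGGAACAG,TGCGATACCGCGATCTCCTT,e2-e3,chr1:5279^9274(+),150,59.87,59.79,0.60,0.55,83.87,1.16,1.26,T1,,,0,1,False
P006,CGGTGTGTGAACCGGAACAG,AGTGTGCGATACCGCGATCT,e2-e3,chr1:5279^9274(+),154,59.87,60.08,0.60,0.55,83.85,1.16,1.26,T1,,,0,1,False
P053,AATGTCTGCGTTGACACGGC,AGTGGATCTGTGCCACCCTG,e3-e4,chr1:9366^11411(+),88,60.22,60.15,0.55,0.60,80.41,1.18,1.28,T1,,,0,1,False
P004,TCGGTGTGTGAACCGGAACA,AGTGTGCGATACCGCGATCT,e2-e3,chr1:5279^9274(+),155,60.29,60.08,0.55,0.55,83.89,1.08,1.28,T1,,,0,2,False
P001,TGACGGTAAGCACCGCTGTA,CTGTTCCGGTTCACACACCG,e2-e3,chr1:5279^9274(+),138,59.86,59.87,0.55,0.60,83.34,1.02,1.32,T1,,,0,3,False
P051,ATTTCCGAGGCTCGGTGTGT,AGTGGATCTGTGCCACCCTG,e3-e4,chr1:9366^11411(+),130,60.15,60.15,0.55,0.60,82.99,1.04,1.34,T1,,,0,3,False
P052,ATTTCCGAGGCTCGGTGTGT,CAGTGGATCTGTGCCACCCT,e3-e4,chr1:9366^11411(+),131,60.15,60.15,0.55,0.60,82.91,1.04,1.34,T1,,,0,3,False
P005,ATGACGGTAAGCACCGCTGTA,CTGTTCCGGTTCACACACCG,e2-e3,chr1:5279^9274(+),139,59.94,59.87,0.52,0.60,83.20,1.13,1.43,T1,,,0,3,False
P003,AACTCCGACGTTGGGCGTAT,TGTTCCGGTTCACACACCGA,e2-e3,chr1:5279^9274(+),173,60.22,60.29,0.55,0.55,84.10,1.08,3.28,T1,T2,,0,2,False
P002,TACACCCAGAAAGCGCGAGT,TGTTCCGGTTCACACACCGA,e2-e3,chr1:5279^9274(+),196,60.15,60.29,0.55,0.55,84.58,1.08,3.28,T1,T2,,0,2,False
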