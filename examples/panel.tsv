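#umi_length	12
#anchor_seq	ACGCAGTCGT
#min_reads_per_umi	3
name	gene	contig	start	end	amplicon_seq
TP53_A	TP53	chr17	7674000	7674100	TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACAAGTCTTTGCGCCCATAAATGTAGCCAGTGAGCTTAGTTGGAGCAAGGGGT
TP53_B	TP53	chr17	7674150	7674250	GCGGAAGCGCAACTCCGTCGCGCGGGTAGCCAACTACTTAAGACCTAGGATTCTGTTGCAGATTAGAACTTGGGACTCAAGATTGCTGCCCTAAGCTATA
TP53_C	TP53	chr17	7674300	7674400	CTAGGCAGCTGCAGCGTCTGGTTTTACTCAGTGTGATCTTTATGCTTGAGAAAATCAACCCTTGTCACATACATAGTGTTTGGGTCTTCCGTAAACAGGT
TP53_D	TP53	chr17	7674450	7674550	GCTTGGCGAGTTCCGCGAAACACTTTGAGGTCAGCGCCATTCAGCGAAGAGCATGTTGTATTGTGTTGTTCAAACACCGATATGAACGAAAGAACCGTTG
TP53_E	TP53	chr17	7674600	7674700	GTCGAGAATGCAATCTTTAAGCTCAACGATCCGTCTCATTTTCAGGCGCGTACGAGTTGTCCAGCTCTAACACGGAAGGTTCACTCTGGAGCTAAGGTGC
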