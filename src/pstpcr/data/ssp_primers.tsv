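id	sequence	kind	annotation	published_tm	published_gc	published_lc
5633	GTTGCGGCAGGTCCTCACCcggtgaaacggtcgggaaactagctct	SSP	KM013689:154<-180	63.9	55.6	78
5634	GTTGCGGCAGGTCCTCACCcgtccgatttcggctttaacccgacc	SSP	KM013689:4038->4067	64.0	57.7	73
5635	GTTGCGGCAGGTCCTCACCagatgtagcaagtggctcctctccatgagc	SSP	KM013689:18814->18843	64.5	53.3	83
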