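id	sequence	kind	annotation	published_tm	published_gc	published_lc
5600	GTTGCGGCAGGTCCTCACC	TAIL	-	69.1	68.1	89
5601	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGACGTC	PST	AatII	49.3	56.3	100
5602	GTTGCGGCAGGTCCTCACCnnnnnnnnnnAACGTT	PST	AclI	46.1	43.8	100
5603	GTTGCGGCAGGTCCTCACCnnnnnnnnnnTTCGAA	PST	AssII	45.6	43.8	100
5604	GTTGCGGCAGGTCCTCACCnnnnnnnnnnTGGCCA	PST	BalI	51.0	56.3	100
5605	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGGATCC	PST	BamHI	48.3	56.3	100
5606	GTTGCGGCAGGTCCTCACCnnnnnnnnnnTGATCA	PST	BclI	44.7	43.8	100
5326	GTTGCGGCAGGTCCTCACCnnnnnnnnnnAGATCT	PST	BglII	43.7	43.8	100
5607	GTTGCGGCAGGTCCTCACCnnnnnnnnnnATCGAT	PST	ClaI	44.8	43.8	89
5608	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGAATTC	PST	EcoRI	43.7	43.8	100
5609	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGATATC	PST	EcoRV	42.3	43.8	89
5610	GTTGCGGCAGGTCCTCACCnnnnnnnnnnAAGCTT	PST	HindIII	45.5	43.8	100
5611	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGTTAAC	PST	HpaI	43.6	43.8	100
5612	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGGTACC	PST	KpnI	48.2	56.3	100
5613	GTTGCGGCAGGTCCTCACCnnnnnnnnnnCCATGG	PST	NcoI	49.1	56.3	100
5614	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGCTAGC	PST	NheI	49.3	56.3	89
5615	GTTGCGGCAGGTCCTCACCnnnnnnnnnnCACGTG	PST	PmaCI	50.2	56.3	100
5616	GTTGCGGCAGGTCCTCACCnnnnnnnnnnCTGCAG	PST	PstI	49.7	56.3	100
5617	GTTGCGGCAGGTCCTCACCnnnnnnnnnnCAGCTG	PST	PvuII	49.7	56.3	100
5618	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGAGCTC	PST	SacI	48.8	56.3	100
5619	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGTCGAC	PST	SalI	49.3	56.3	100
5620	GTTGCGGCAGGTCCTCACCnnnnnnnnnnAGTACT	PST	ScaI	43.7	43.8	100
5621	GTTGCGGCAGGTCCTCACCnnnnnnnnnnGCATGC	PST	SphI	50.9	56.3	89
5622	GTTGCGGCAGGTCCTCACCnnnnnnnnnnAGGCCT	PST	StuI	50.1	56.3	100
5327	GTTGCGGCAGGTCCTCACCnnnnnnnnnnTCTAGA	PST	XbaI	43.1	43.8	100
5623	GTTGCGGCAGGTCCTCACCnnnnnnnnnnCTCGAG	PST	XhoI	48.6	56.3	100
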