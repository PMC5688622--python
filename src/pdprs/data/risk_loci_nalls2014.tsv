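variant_id	chrom	pos	gene	effect_allele	ref_maf	or	study_maf	call_rate	weight
rs35749011	1	155135036	GBA-SYT11	A	0.017	2.307	0.021	0.999	1.206
rs823118	1	205723572	RAB7L1-NUCKS1	T	0.559	1.109	0.412	0.945	0.149
rs10797576	1	232664611	SIPA1L2	T	0.140	1.110	0.142	0.125	NA
rs6430538	2	135539967	ACMSD-TMEM163	T	0.430	0.882	0.430	0.998	-0.181
rs1474055	2	169110394	STK39	T	0.128	1.218	0.133	0.991	0.285
rs115185635	3	87520857	KRT8P25-APOOP2	C	0.035	0.931	0.035	0.123	NA
rs12637471	3	182762437	MCCC1	A	0.193	0.836	0.183	1.000	-0.258
rs34311866	4	951947	TMEM175-GAK-SGKQ	T	0.809	0.791	0.779	0.998	-0.338
rs11724635	4	15737101	BST1	A	0.553	1.138	0.439	1.000	0.187
rs6812193	4	77198986	FAM47E-SCARB2	T	0.364	0.935	0.347	1.000	-0.097
rs356182	4	90626111	SNCA	A	0.633	0.822	0.599	0.872	-0.085
rs9275326	6	32666660	HLA-DQB1	T	0.094	0.900	0.100	0.995	-0.152
rs199347	7	23293746	GPNMB	A	0.590	1.072	0.595	0.996	0.100
rs117896735	10	121536327	INPP5F	A	0.014	1.404	0.004	0.967	0.147
rs3793947	11	83544472	DLG2	A	0.443	0.976	NA	NA	NA
rs329648	11	133765367	MIR4697	T	0.354	0.121	0.359	0.126	NA
rs76904798	12	40614434	LRRK2	T	0.143	1.110	0.151	0.999	0.151
rs11060180	12	123303586	CCDC62	A	0.558	1.114	0.560	0.872	0.156
rs11158026	14	55348869	GCH1	T	0.335	0.889	0.314	0.123	NA
rs1555399	14	67984370	TMEM229B	A	0.468	0.872	0.509	0.125	NA
rs2414739	15	61994134	VPS13C	A	0.734	1.114	0.781	0.127	NA
rs14235	16	31121793	BCKDK-STX1B	A	0.381	1.094	0.391	0.995	0.130
rs17649553	17	43994648	MAPT	T	0.226	0.771	0.201	0.991	-0.113
rs12456492	18	40673380	RIT2	A	0.693	0.905	0.756	0.126	NA
rs62120679	19	2363319	SPPL2B	T	0.314	1.141	NA	NA	NA
rs8118008	20	3168166	DDRGK1	A	0.657	1.111	0.609	0.126	NA
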