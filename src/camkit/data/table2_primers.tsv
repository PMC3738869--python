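marker	zf_origin	ch_chrom	ch_pos	zf_len	evalue	dye	f_seq	r_seq	degen_pair	f_pctid	f_mm	r_pctid	r_mm	z_linked
CAM-01	Contig4.1379:6555-6992	chr2	67828480	437	9e-147	HEX	AAAGGCCAAGRCCAGTATG	CTCTCATCCACCCTGTTAGC	1	100	0	100	0	0
CAM-02	Contig5.1371:163550-163981	chr7	22132454	431	1.1e-96	6-FAM	GAATTAAAGAYAGCAGATGCAGG	AGCTGATGAAATGAGAATGCAG	1	100	0	100	0	0
CAM-03	Contig5.1597:35280-35767	chr7	24391832	487	2.2e-70	HEX	ATTAGCATAGCTCAGCATTGCC	CGAGCATTCAAMCCTGTCATC	1	91	2	95	1	0
CAM-04	Contig8.649:3118-3539	chr1	133721521	421	6e-133	6-FAM	TACCTCTGGCYAAGGAACTG	GCTCAGAACATCAATCACTGC	1	90	2	100	0	0
CAM-05	Contig12.77:11232-11665	chr1	47660443	433	2.4e-72	6-FAM	TTACACAGACTGCAAACCGC	CTGTTKCTCTAGTAATGAGATCCTG	1	100	0	92	2	0
CAM-06	Contig12.342:17413-17858	chr1	52304006	445	9e-115	HEX	GTGATGGTCCAGGTCTTGC	CAAGAGGAACAGATGAGGGTC	0	100	0	100	0	0
CAM-07	Contig12.442:2629-3062	chr1	53412026	433	2e-113	HEX	AAATGATGAGRTCTGGGTGAG	CCATTTCCAAGWGATTTGC	2	100	0	100	0	0
CAM-08	Contig13.893:13419-13850	chr10	516461	431	5e-79	6-FAM	AGAARAAGCCACCCTCACAG	CTCGTTTCCATTGGCGTTG	1	100	0	95	1	0
CAM-09	Contig15.537:32597-33018	chr4	17039238	421	1.6e-79	HEX	AGAYACACAGCCACCCCAGAG	CACWTGTATCCACAYGCTGAC	3	86	3	90	2	0
CAM-10	Contig16.130:3866-4309	chr13	1070809	429	4.4e-67	6-FAM	TATCCMGAGAATGGGCATC	KGCTCTCATTGTCATGCTG	2	89	2	95	1	0
CAM-11	Contig17.242:5423-5868	chrZ	7888318	445	1.7e-89	HEX	TGGTACAGGGACAGCAAACC	AGATGCTGRGAGCGGATG	1	100	0	100	0	1
CAM-12	Contig23.425:77718-78157	chr2	62785492	439	1e-95	6-FAM	TGGCARTAAWTCCAGAGATTACC	CTGRCATTTGTCTTAAGCGTG	3	100	0	95	1	0
CAM-13	Contig28.55:8348-8785	chr6	28449965	437	4e-140	HEX	TCAAATACAGCAGCAGGCAG	TTCATTACCAAACAGCATCCAG	0	100	0	100	0	0
CAM-14	Contig32.413:24503-24950	chr9	5323789	447	2.3e-92	6-FAM	GYAAGTGAAAGCTAAAGAAAGCC	GGCAGTTCCAGCCATTTAC	1	100	0	100	0	0
CAM-15	Contig49.62:16781-17206	chr1	73032096	425	9e-105	6-FAM	SGACGACTCCTTTATTTCCC	TTCTGACTTCCYCAGGTAACAC	2	90	2	100	0	0
CAM-16	Contig50.513:25871-26302	chr17	4598995	431	1.1e-85	HEX	AGCCTTGATMTTGGGAAGAGC	ATCCATACTCYGTGCAACCTG	2	90	2	100	0	0
CAM-17	Contig56.179:11880-12303	chr3	10551236	423	5e-141	6-FAM	CGGGTTGTAATCAAGAAGATGC	CTGCGGAGCAATTAACGC	0	100	0	100	0	0
CAM-18	Contig61.97:37926-38358	chr3	31888225	432	1e-106	HEX	TTAAGAAGTTTACACCCAGCG	GCTAAATAACAGAGCCAGGAAG	0	100	0	100	0	0
CAM-19	Contig69.248:5308-5739	chr1	199733800	431	4e-119	6-FAM	TCTTGGAGGCAGATARGAAGTG	GAGCAAGCAAAGATCACAAGC	1	100	0	100	0	0
CAM-20	Contig70.196:1579-2012	chr24	2939427	433	9e-105	HEX	TAACAGGCAGGAATGCAGG	TCAGCCAGTGTTGGAGGTC	0	100	0	100	0	0
CAM-21	Contig74.100:2226-2651	chr2	2408229	425	1.1e-96	6-FAM	TGGGAGAACATTATAGCGTGAG	TTGAAATGRGAACCACGGAC	1	100	0	95	1	0
CAM-22	Contig75.34:11916-12343	chr18	6214289	427	1.2e-76	HEX	RAGRGCCACTTTCACTCCTG	ATGCTGTGACACTKGGAGGC	3	90	2	100	0	0
CAM-23	Contig83.70:49198-49633	chr6	31243934	435	2e-142	6-FAM	CTCCACTTAGCTTGTAAATGCAC	CCAAGRAGTGCCCTAGATGTC	1	96	1	100	0	0
CAM-24	Contig122.74:8163-8588	chr1	2092872	425	1.8e-59	HEX	CCCACTTCAGTCTTCAGAGC	TGGAGTATTTGGGATTGGAG	0	100	0	100	0	0
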