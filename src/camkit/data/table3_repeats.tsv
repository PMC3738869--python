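marker	motif	zf_struct	ch_struct	zf_longest	ch_longest	zf_chrom	zf_pos	zf_n	zf_alleles	zf_exp_len	zf_min_allele	zf_obs_range	ch_n	ch_alleles	ch_exp_len	ch_min_allele	ch_obs_range
CAM-01	CA	(A)3(CA)18	(A)3(CA)13	18	13	Tgu2	42810182	12	6	323	284	306-345	4	2	323	294	323,325
CAM-02	CA	(CA)16	(CA)10CG(CA)9	16	10	Tgu7	12381541	11	9	373	341	365-389	4	1	350	310	346
CAM-03	TG	(TG)5TC(TG)5TC(TG)3TC(TG)27	(GA)2CCTCCTC(TG)5(TA)2(TG)14	27	14	Tgu7	9747717	12	11	209	123	168-269	4	2	164	111	153,163
CAM-04	GA	(GA)11	(GA)11	11	11	Tgu1	34220431	12	3	283	261	278-284	4	1	275	253	275
CAM-05	CA	(CA)17	(CA)3GACATA(CA)12(C)4GGCCG(A)13CAACC(A)14C(G)4(A)7	17	12	Tgu1A	45129155	7	6	216	182	206-223	4	2	198	109	194,197
CAM-06	AT	(AT)4GT(AT)8TTATGT(AT)7	(AT)11(W)4G(TA)6(W)13G(T)3	8	11	Tgu1A	49994076	8	5	284	190	283-295	4	1	278	190	278
CAM-07	CT	(CT)3CC(CT)17	(CT)6CC(CT)11	17	11	Tgu1A	51267786	12	6	234	153	233-265	3	1	234	166	235
CAM-08	TA	(T)6(TA)9AA(TA)6	(T)5(TA)8AA(TA)6	9	8	Tgu10	3390752	12	1	224	157	220	4	1	221	186	219
CAM-09	GT	(GT)11	(GT)14	11	14	Tgu4A	8999969	11	8	325	303	314-324	4	2	324	294	166,193
CAM-10	GT	(GT)22	(GT)15	22	15	Tgu13	16024201	11	8	201	157	183-210	2	1	183	153	186
CAM-11	GT	(GT)23	(GT)11	23	11	TguZ	39096210	12	6	147	101	145-157	4	1	123	101	117
CAM-12	CA	(CA)20	(CA)2GA(CA)2CGCGTG(CA)2CG(CA)3TA(CA)13	20	13	Tgu2	70094313	12	9	370	330	371-433	3	2	346	290	346,348
CAM-13	TC	(A)26G(A)3G(A)4G(A)5G(A)3G(A)5GCAAC(TG)2(TC)6TT(TC)12C(T)10	(TC)5T(TC)16(C)4(T)13	12	16	Tgu6	26899281	12	7	233	106	225-232	4	1	229	101	223
CAM-14	CA	(CA)24TG(CA)6	(CA)13	24	13	Tgu9	5387194	12	8	365	136	346-377	4	2	353	327	352,354
CAM-15	GA	(GA)13	(GA)7GG(GA)2GG(GA)13	13	13	Tgu1A	61859791	12	3	266	240	260-266	4	2	273	178	247,249
CAM-16	CA	(CA)16	(CA)15	16	15	Tgu17	4369074	11	5	290	258	287-301	3	1	310	280	301
CAM-17	TG	(T)9G(GT)4CC(TG)2(TC)3(TG)12	(T)3(TG)14(CG)4(TG)2CGG(TG)4	12	14	Tgu3	2816652	12	6	209	132	205-218	3	2	207	153	204,208
CAM-18	TA&TG	(TA)11T(TA)5(TG)7&(AT)6	(TA)10T(TA)5(TG)11&(TA)4	11	11	Tgu3	31630754	12	6	342	159	336-348	2	1	347	185	348
CAM-19	GT	(GA)3(GT)6TT(GT)9	(T)3(GT)20	9	20	Tgu1	112898014	12	6	231	180	227-248	4	1	228	156	227
CAM-20	AT	(AT)5TT(AT)11&(A)12G(A)7	(AT)3AA(AT)9&(AT)5&(A)14	11	9	Tgu24	5214087	12	6	194	61	185-193	2	1	187	75	182
CAM-21	TG	(TG)13	(TG)12	13	12	Tgu2	2028140	12	4	277	251	265-274	4	1	287	263	287
CAM-22	GT	(A)8&(GT)13	(A)5&(A)6&(GT)12	13	12	Tgu18	10770012	12	5	137	95	134-152	4	2	134	88	126,131
CAM-23	TG	(TG)18(AG)5GC(AG)3	(TG)5TC(TG)11TT(AG)9	18	11	Tgu6	30010998	12	5	147	93	140-151	4	1	147	93	149
CAM-24	CA	(CA)3(CG)2(CA)13	(GA)4(CA)2CG(CA)2CGCACT(CA)15	13	15	Tgu1A	1456627	12	6	119	86	111-125	4	1	121	67	111
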