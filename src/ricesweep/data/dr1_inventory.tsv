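# DR-I block inventory; diversity/divergence columns in units of 1e-5 per bp
chrom	start	end	relaxed	pi_jap	pi_tro	pi_tem	pi_ind	dxy_jap_ind	dxy_tro_ind	dxy_tem_ind	pi_wild	dxy_jap_wild	dxy_ind_wild
chr01	35499730	35510003	0	4	2	6	14	242	246	241	89	178	121
chr01	35839043	35890683	1	19	10	13	21	468	478	467	232	320	263
chr02	13139975	13160003	0	18	5	6	18	295	305	301	133	209	142
chr02	13349983	13360044	0	13	2	4	11	241	249	246	101	149	131
chr02	14944936	14962544	0	15	3	4	14	250	260	252	121	157	145
chr02	27708263	27721727	0	11	4	11	14	263	271	263	87	143	145
chr03	1579192	1602557	0	16	4	15	14	302	307	311	153	183	193
chr03	2483329	2542460	1	16	20	9	25	434	444	435	198	275	239
chr03	2706518	2724355	0	13	18	7	18	440	453	440	188	310	210
chr03	2832279	2854311	0	3	3	4	16	304	310	306	214	210	243
chr03	2896026	2923841	0	5	3	5	15	321	327	323	151	178	220
chr03	2997394	3195565	1	18	11	22	21	578	590	580	260	356	316
chr03	3479756	3498823	0	3	2	3	14	241	245	243	132	180	138
chr03	24189350	24230136	1	20	14	28	22	504	511	508	289	341	306
chr03	28469725	28489493	0	14	21	7	12	429	437	427	245	327	308
chr04	34409908	34420007	0	13	6	15	19	314	316	319	159	216	176
chr04	34469603	34500654	0	14	6	16	16	262	264	265	123	169	136
chr05	21659599	21670204	1	16	7	25	21	289	295	291	156	177	202
chr05	22789981	22800012	0	17	6	16	15	319	328	331	472	379	421
chr05	22869880	22880236	0	6	2	3	17	295	305	302	137	155	208
chr05	24026607	24070766	0	20	9	35	18	604	614	616	318	438	349
chr05	24300403	24330214	0	16	8	13	11	343	356	350	348	346	329
chr05	26824033	26840483	0	11	2	4	17	233	243	239	131	172	137
chr07	4149981	4163826	0	9	8	2	18	214	220	217	420	365	365
chr07	25598750	25620217	0	8	10	5	16	323	327	323	155	219	190
chr09	22759164	22771433	0	6	1	3	18	251	258	254	171	164	204
chr09	22910542	22930021	0	14	8	11	18	345	356	349	242	251	256
chr10	21289972	21400480	1	18	10	12	23	517	534	521	250	336	263
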