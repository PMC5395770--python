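# DR-II block inventory; diversity/divergence columns in units of 1e-5 per bp
chrom	start	end	relaxed	pi_jap	pi_ind	dxy_jap_ind	pi_cul	pi_wild	dxy_jap_wild	dxy_ind_wild	dxy_cul_wild
chr01	8645929	8660126	0	11	8	16	13	118	104	108	106
chr03	26199939	26210003	0	10	15	14	13	141	140	144	142
chr04	25959995	26040007	0	10	15	14	13	181	228	229	229
chr04	26089892	26100078	0	6	8	7	7	155	250	249	249
chr04	26229998	26260103	0	10	15	15	14	230	327	325	326
chr04	26359991	26370003	0	5	6	6	6	125	168	166	167
chr04	26789966	26810053	0	10	16	14	14	155	251	247	249
chr04	26949945	26970083	0	9	14	13	12	141	191	190	190
chr04	27009995	27060009	0	7	20	17	16	286	360	356	358
chr04	32529159	32540000	0	18	13	16	16	109	104	123	114
chr04	33889971	33900005	0	15	10	20	16	173	228	222	225
chr04	33979989	33990038	0	15	10	16	14	100	135	145	140
chr04	34219891	34249999	0	12	7	12	11	277	316	319	318
chr05	29729953	29740204	0	9	5	7	7	115	115	103	109
chr07	2739991	2770008	0	15	13	18	16	406	456	451	453
chr07	2799992	2810002	0	1	16	9	9	262	311	305	308
chr07	2879923	2910069	0	14	10	13	13	280	437	432	434
chr07	2979996	2991842	0	1	4	3	3	140	104	105	105
chr07	3096102	3109999	0	10	9	11	10	110	116	108	112
chr07	3699995	3710053	0	12	7	10	10	364	394	396	395
chr07	3759873	3790006	0	9	7	10	9	264	273	272	273
chr07	4019981	4030093	0	12	6	12	10	138	131	124	127
chr07	4070000	4090006	0	9	17	15	14	236	256	252	254
chr08	23749999	23770091	0	12	14	14	14	246	269	263	266
chr08	23809970	23860036	0	9	16	15	14	549	500	501	501
chr08	23919999	23940003	0	5	10	9	8	206	283	282	283
chr08	23989975	24040080	0	7	14	11	11	273	315	312	313
chr12	24930000	24950016	0	13	1	11	9	168	124	121	122
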