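gene	total_snps	lt_0_2	from_0_2_to_0_5	from_0_5_to_2	from_2_to_5	gt_5
CYP1A1	86	0	1	0	0	0
CYP1A2	130	0	4	1	0	0
CYP2A6	231	0	3	2	0	0
CYP2A13	188	0	1	0	1	0
CYP2B6	584	0	0	4	1	0
CYP2C8	591	1	2	8	0	0
CYP2C9	981	0	0	3	2	0
CYP2C18	1935	0	1	4	0	0
CYP2C19	2908	1	1	7	4	0
CYP2D6	153	0	0	3	1	0
CYP2E1	965	1	1	5	2	0
CYP2F1	336	0	4	1	0	0
CYP3A4	331	0	0	0	2	0
CYP3A5	424	0	0	0	2	0
CYP3A7	387	0	1	1	0	0
CYP3A43	548	0	0	10	1	0
CYP2J2	436	0	0	0	0	0
CYP2U1	334	0	1	2	9	0
CYP4A11	238	0	0	2	0	0
CYP4B1	1218	3	6	7	1	0
CYP4F11	547	1	0	1	2	0
CYP4F12	313	1	1	11	0	0
CYP4F22	877	0	23	4	4	0
CYP4V2	510	0	3	2	1	1
CYP4F2	409	1	5	0	1	0
CYP4F3	653	0	0	37	5	1
CYP4F8	313	0	1	16	0	1
CYP5A1	4394	0	12	19	6	0
CYP8A1	1074	3	13	10	1	1
CYP2R1	184	0	2	1	0	0
CYP24A1	424	0	0	4	5	1
CYP26A1	123	0	3	0	1	0
CYP26B1	366	0	0	5	3	1
CYP26C1	269	0	1	0	2	0
CYP27B1	79	0	0	0	0	0
CYP27C1	754	1	14	10	26	1
CYP1B1	977	0	1	2	1	0
CYP7A1	157	0	0	3	0	0
CYP7B1	2849	0	3	6	1	5
CYP8B1	54	1	1	4	0	0
CYP11A1	413	0	0	0	1	0
CYP11B1	205	0	0	0	0	0
CYP11B2	212	0	3	1	1	0
CYP17A1	99	0	0	2	0	0
CYP19A1	2022	0	1	56	1	0
CYP21A2	102	0	0	0	0	0
CYP27A1	475	0	0	15	0	0
CYP39A1	1700	0	6	4	4	2
CYP46A1	27	0	4	15	6	0
CYP51A1	986	1	2	2	5	0
CYP2A7	246	0	0	2	0	0
CYP2S1	279	0	5	7	6	0
CYP2W1	173	0	4	9	1	0
CYP4A22	233	0	0	0	0	0
CYP4X1	385	0	0	0	0	0
CYP4Z1	781	0	0	0	0	0
CYP20A1	1011	3	4	57	2	2
AdR	183	0	0	0	0	0
Adx	667	0	1	18	1	0
POR	1797	2	2	28	4	0
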