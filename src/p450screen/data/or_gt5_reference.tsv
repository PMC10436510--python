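gene	snp	or	ci_low	ci_high	p	comparison	mode
CYP4V2	rs138504382	10.023	1.263	79.564	0.029	GPD/GUN	het_only
CYP24A1	rs146156359	10.023	1.263	79.564	0.029	GPD/GUN	het_only
CYP39A1	rs141849577	10.023	1.263	79.564	0.029	GPD/GUN	het_only
CYP39A1	chr646616193_TCCCTCCCTC	5.055	1.059	24.130	0.042	GPD/GUN	het_only
CYP4F8	rs189015704	8.880	1.104	71.405	0.040	GPD/GUN	het_only
CYP7B1	rs117323804	8.880	1.104	71.405	0.040	GPD/GUN	het_only
CYP7B1	rs117554868	8.880	1.104	71.405	0.040	GPD/GUN	het_only
CYP7B1	rs199716748	8.880	1.104	71.405	0.040	GPD/GUN	het_only
CYP7B1	rs149196751	8.880	1.104	71.405	0.040	GPD/GUN	het_only
CYP7B1	rs138019891	8.880	1.104	71.405	0.040	GPD/GUN	het_only
CYP27C1	chr2127204448_G	6.249	1.370	28.510	0.018	GUN/GPD	het_only
CYP4F3	chr1915651701_TTATGTCT	6.167	1.356	28.044	0.019	GPD/GUN	het_only
CYP26B1	chr272144944_GA	6.147	1.352	27.952	0.019	GPD/GUN	het_only
CYP20A1	rs4673253	5.379	1.793	16.139	0.003	GPD/GUN	hom_only
CYP20A1	rs79425344	5.379	1.793	16.139	0.003	GPD/GUN	hom_only
CYP8A1	rs112853036	5.269	1.500	18.512	0.010	GPD/GUN	het_only
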