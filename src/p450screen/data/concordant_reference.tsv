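gene	snp	or_gpd_gun	or_gpd_hc
CYP2C8	rs34115801	1.46	2.1
CYP2C8	rs10882520	1.44	2
CYP2C8	rs1341162	1.44	2
CYP2C8	rs1934978	1.4	2
CYP2C8	rs11572078	1.4	2
CYP2C8	rs12246157	1.4	2
CYP2C8	rs78705198	1.4	2
CYP2C8	rs1113129	1.4	2
CYP2C8	rs191305096	0.4	0.3
CYP2C8	rs117072179	0.41	0.3
CYP2D6	chr22_4212700_GA	1.6	2.2
CYP2D6	chr22_42127207_CT	1.6	2.1
CYP2D6	chr22_42127941_GA	1.5	1.8
CYP2C9	rs147118402	1.8	2.3
CYP2C9	chr10_94954906_TTTTTA	1.5	2.4
CYP2A6	rs2002976	0.45	0.33
CYP2F1	chr19_41119717_CTCTCTCTATATATATA	0.2	0.22
CYP3A4	rs28371763	2.6	2.9
CYP4B1	rs201934421	3.3	3.4
CYP4B1	rs60103736	0.16	0.14
CYP4B1	rs60103736	0.24	0.21
CYP4B1	chr1_46800204_TTTCTCTTC	0.1	0.09
CYP4B1	chr1_46800203_CTTTCTTC	0.11	0.1
CYP4B1	chr1_46782839_CTCTT	1.4	1.6
CYP4B1	rs72286736	0.27	0.18
CYP4V2	rs59350227	0.7	0.58
CYP4V2	chr4_186204405_CGGTGGAGACGTTTCGCTGGCGTAAGAGGTGGAGGTGGAGA	0.56	0.56
CYP4F11	rs3930732	0.66	0.55
CYP5A1	chr7_139950037_ATTTTTTATT	0.4	0.18
CYP5A1	chr7_139778328_TTTG	0.28	0.21
CYP5A1	rs143131884	0.30	0.21
CYP5A1	rs191028344	0.30	0.26
CYP5A1	rs62490128	0.2	0.11
CYP5A1	rs2008582	0.53	0.32
CYP5A1	rs78396607	0.56	0.52
CYP5A1	rs2299899	1.67	3.16
CYP5A1	rs10260531	0.56	0.52
CYP5A1	rs57244136	0.56	0.52
CYP5A1	rs10234650	1.39	1.79
CYP5A1	rs2299897	2.28	4.44
CYP5A1	rs5887946	2.13	5.22
CYP4F3	rs4807965	2.31	2.24
CYP4F3	rs1915380	0.68	0.65
CYP4F3	rs28371492	0.68	0.65
CYP4F3	rs28371541	2.99	10.21
CYP4F3	rs139791776	0.60	0.69
CYP4F3	rs2733751	0.71	0.66
CYP4F3	rs2683041	0.71	0.65
CYP8A1	rs77401275	0.32	0.33
CYP26B1	rs61138718	0.65	0.63
CYP26B1	rs3768647	0.62	0.63
CYP26B1	rs3768644	0.58	0.48
CYP26B1	rs10166057	0.54	0.42
CYP24A1	rs6022987	1.51	1.62
CYP24A1	rs2762935	1.55	1.55
CYP39A1	chr6_46616152_CTTTCTTTCTTTC	0.5	0.47
CYP39A1	chr6_46616154_TTCTTTC	0.56	0.56
CYP39A1	chr6_46616156_CTTTCTTTTTTCTCTTTCT	0.5	0.43
CYP39A1	chr6_46627420_TTA	1.45	1.57
CYP51A1	rs112952169	0.61	0.52
CYP51A1	chr7_92128463_CGTC	0.66	0.63
CYP8B1	rs6782601	0.19	0.09
CYP8B1	rs735320	0.24	0.18
CYP7A1	rs8192879	1.61	1.51
CYP46A1	rs76169349	0.51	0.36
CYP2W1	chr7_988002_GGGGGGGTCCCCTCTGTGTGTCCT	0.42	0.38
CYP2W1	rs2272375	0.66	0.67
POR	rs10225188	0.51	0.65
POR	rs9886105	0.52	0.64
POR	rs10239977	0.53	0.65
POR	rs13231817	0.53	0.66
POR	rs11764251	0.53	0.67
POR	rs35350121	0.55	0.68
POR	rs116971685	0.41	0.47
POR	rs377474536	0.13	0.20
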