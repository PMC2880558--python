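gene_symbol	maf	snp_id	n	p_women	p_men	p_overall
F13A1	0.252	rs2274393	20812	0.0084	0.1413	0.0030
ST3GAL6	0.463	rs865474	20789	0.0571	0.0350	0.0050
F13A1	0.433	rs406238	20782	0.0077	0.2417	0.0051
ST3GAL6	0.294	rs7628381	20795	0.0266	0.1016	0.0059
RNASE4	0.269	rs3094	20718	0.0021	0.6363	0.0074
C20orf198	0.156	rs1739652	4584	0.0599	0.0599	0.0078
F13A1	0.152	rs11243069	20805	0.0095	0.3712	0.0097
F13A1	0.220	rs9504743	20806	0.0991	0.0414	0.0103
C16orf62	0.337	rs3782323	20812	0.0616	0.0782	0.0104
PRDX8	0.262	rs6675929	20797	0.0287	0.1753	0.0107
SH3BGR	0.234	rs2837035	20806	0.0338	0.1876	0.0133
IVNS1ABP	0.433	rs1889976	20807	0.0825	0.0876	0.0152
SH3BGRL	0.261	rs5959087	20814	0.0741	0.1159	0.0173
SH3BGRL	0.262	rs12389790	20777	0.0816	0.1122	0.0185
SPSB3	0.176	rs17559	16029	0.0022	0.9365	0.0189
F13A1	0.266	rs9328347	20808	0.1760	0.0474	0.0211
F13A1	0.347	rs387528	4572	0.1031	0.1031	0.0212
F13A1	0.185	rs3024443	20813	0.2437	0.0271	0.0216
AATF	0.214	rs11871099	20803	0.1250	0.0825	0.0223
AATF	0.342	rs1564796	20781	0.1268	0.0869	0.0233
IVNS1ABP	0.431	rs10911707	4574	0.1323	0.1323	0.0333
TMEM101	0.432	rs1618809	20778	0.1937	0.1183	0.0458
EIF4EBP1	0.223	rs6605631	4584	0.1633	0.1633	0.0486
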