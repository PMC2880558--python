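gene_symbol	probe_id	pearson_r	p_unrelated	fold_obese_lean	p_twin
SAP30BP	217965_s_at	-0.51	9.99e-05	1.00	0.56
MRPL9	209609_s_at	-0.43	9.57e-05	0.89	0.72
C20orf198	226149_at	-0.35	9.26e-05	0.93	0.45
IVNS1ABP	206245_s_at	0.46	8.86e-05	1.24	0.08
SPSB3	46256_at	-0.52	8.32e-05	0.93	0.06
SART1	200051_at	-0.34	8.29e-05	1.01	0.83
ST3GAL6	210942_s_at	-0.52	8.27e-05	0.77	0.05
FAHD2A	222056_s_at	-0.41	8.05e-05	0.97	0.53
mRNA AK125162	231040_at	-0.42	7.95e-05	0.83	0.85
SH3BGR	204979_s_at	0.32	5.0e-05	1.13	0.11
NPY1R	205440_s_at	0.42	5.0e-05	1.15	0.14
EIF2B4	209429_x_at	-0.48	4.83e-05	1.07	0.62
EIF4EBP1	221539_at	-0.54	4.55e-05	0.82	0.08
AATF	209165_at	-0.46	4.26e-05	1.03	0.44
PRDX6	200844_s_at	-0.48	3.39e-05	0.93	0.18
SH3BGRL	201312_s_at	0.38	3.33e-05	1.12	0.18
PCBD1	203557_s_at	-0.56	3.1e-05	0.88	0.05
PRSS23	226279_at	0.33	2.78e-05	1.11	0.07
BC007882	225657_at	-0.28	2.72e-05	0.96	0.67
ST3GAL6	213355_at	-0.47	2.48e-05	0.97	0.24
TMEM101	225004_at	-0.36	1.79e-05	0.96	0.11
F13A1	203305_at	0.41	9.59e-06	1.13	0.11
TRAP1	201391_at	-0.38	6.53e-06	0.98	0.43
CRY2	212695_at	-0.41	5.35e-06	0.92	0.22
PPIE	210502_s_at	-0.6	4.9e-06	0.97	0.54
C16orf62	225772_s_at	-0.43	4.9e-06	0.83	0.06
RNASE4	213397_x_at	-0.44	2.68e-06	0.86	0.09
HADHA	208630_at	-0.5	2.5e-06	1.03	0.35
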