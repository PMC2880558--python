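gene_symbol	maf	snp_id	n	p_women	p_men	p_overall
URB	0.457	rs9870432	20574	0.0008	0.2973	0.0012
URB	0.314	rs6807798	20659	0.0010	0.5546	0.0036
URB	0.384	rs10511316	20644	0.0015	0.5113	0.0040
URB	0.372	rs2279531	20613	0.0095	0.4464	0.0130
FLJ45244	0.148	rs3814816	20437	0.1010	0.0631	0.0147
C12orf30	0.160	rs7297415	20657	0.0856	0.1071	0.0189
PALLD	0.467	rs7670597	20654	0.6463	0.0028	0.0249
CIDEA	0.376	rs6505744	20658	0.1039	0.1397	0.0282
DAPK2	0.024	rs2034099	4427	0.0019	0.8398	0.0293
MRC1	0.089	rs537085	4407	0.2544	0.0531	0.0304
ABCC1	0.431	rs3887893	20657	0.0749	0.2300	0.0323
ADAM12	0.288	rs1459709	20665	0.1430	0.1125	0.0326
CCL2	0.322	rs991804	20666	0.1117	0.1547	0.0329
ADAM12	0.493	rs1278377	20654	0.0127	0.7924	0.0363
CLMN	0.375	rs12894609	20650	0.0696	0.2778	0.0364
PALLD	0.470	rs6852874	20311	0.1212	0.1719	0.0390
CCL2	0.388	rs4795893	20661	0.0201	0.6731	0.0391
ABCC1	0.131	rs16967126	20653	0.6589	0.0058	0.0397
ABCC1	0.167	rs152029	20658	0.0362	0.5482	0.0443
PALLD	0.429	rs17542430	20623	0.4509	0.0274	0.0471
CPVL	0.194	rs245857	20587	0.3262	0.0525	0.0472
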