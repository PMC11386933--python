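id	log2fc	pvalue	circbase_id	regulation
ENSG00000172766	19.06135514	7.65E-06	hsa_circ_0030069	UP
ENSG00000274070	18.46972573	0.000488819	-	UP
ENSG00000112640	18.46972573	0.000488819	hsa_circ_0076437	UP
ENSG00000134802	18.46972573	0.000488819	hsa_circ_0022132	UP
ENSG00000175198	18.19335738	0.00195459	hsa_circ_0030754	UP
ENSG00000109323	18.16027292	0.00195459	hsa_circ_0001432	UP
ENSG00000145216	18.14779764	0.003908594	hsa_circ_0069737	UP
ENSG00000105246	18.14779764	0.003908594	-	UP
ENSG00000077420	18.06135514	0.003908594	hsa_circ_0017997	UP
ENSG00000198431	18.04384835	0.003908594	hsa_circ_0027960	UP
ENSG00000171735	17.96503518	0.003908594	hsa_circ_0009542	UP
ENSG00000133961	17.95515256	0.007816146	hsa_circ_0008406	UP
ENSG00000198131	17.95515256	0.007816146	hsa_circ_0000967	UP
ENSG00000149311	17.94075341	0.007816146	hsa_circ_0024229	UP
ENSG00000152359	17.92620909	0.007816146	hsa_circ_0073053	UP
ENSG00000141298	17.92620909	0.007816146	hsa_circ_0042820	UP
ENSG00000175198	17.73276014	0.015630469	hsa_circ_0030754	UP
ENSG00000139324	17.73276014	0.015630469	hsa_circ_0027691	UP
ENSG00000162772	17.73276014	0.015630469	-	UP
ENSG00000137767	17.73276014	0.015630469	-	UP
ENSG00000096717	17.73276014	0.015630469	hsa_circ_0018471	UP
ENSG00000173064	17.73276014	0.015630469	-	UP
ENSG00000089248	17.73276014	0.015630469	-	UP
ENSG00000133624	17.73276014	0.015630469	-	UP
ENSG00000122218	17.73276014	0.015630469	hsa_circ_0014908	UP
ENSG00000135919	17.73276014	0.015630469	hsa_circ_0008365	UP
ENSG00000114062	17.71594709	0.015630469	hsa_circ_0034165	UP
ENSG00000105939	17.71594709	0.015630469	hsa_circ_0082622	UP
ENSG00000152061	17.68172151	0.015630469	hsa_circ_0015334	UP
ENSG00000102921	17.66429935	0.015630469	hsa_circ_0039316	UP
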