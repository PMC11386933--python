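id	log2fc	pvalue	symbol	regulation
ENSG00000283149	-9.373590215	0.048177772	-	DOWN
ENSG00000285238	-9.120669887	0.047017499	-	DOWN
ENSG00000196826	-6.594946589	0.005950249	-	DOWN
ENSG00000256407	6.196397213	0.020316197	-	UP
ENSG00000120903	5.984893108	0.015972752	CHRNA2	UP
ENSG00000269693	5.824428435	0.044393428	-	UP
ENSG00000243708	4.14974712	0.006466558	PLA2G4B	UP
ENSG00000268400	3.857980995	0.000344882	-	UP
ENSG00000180574	-3.64385619	0.044530877	EIF2S3B	DOWN
ENSG00000203618	-3.087462841	0.04459388	GP1BB	DOWN
ENSG00000258644	2.669278787	0.011001883	SYNJ2BP-COX16	UP
ENSG00000286237	2.662965013	0.037227607	ARMCX5-GPRASP2	UP
ENSG00000285130	-2.169925001	0.007819973	-	DOWN
ENSG00000285932	-2.073248982	0.00788196	-	DOWN
ENSG00000081853	1.874469118	0.023777064	PCDHGA2	UP
ENSG00000288710	1.811238357	0.028399634	-	UP
ENSG00000205572	-1.739685096	0.031078684	SERF1B	DOWN
ENSG00000224420	1.490050854	0.034327488	ADM5	UP
ENSG00000285953	-1.301790449	0.017034279	-	DOWN
ENSG00000180071	1.206450877	0.038552507	ANKRD18A	UP
ENSG00000270106	-1.108059746	0.014049763	TSNAX-DISC1	DOWN
ENSG00000128917	1.069041644	0.036951898	DLL4	UP
ENSG00000099864	0.951905712	0.036496947	PALM	UP
ENSG00000105655	0.932095935	0.046649885	ISYNA1	UP
ENSG00000254206	0.923131237	0.00536801	NPIPB11	UP
ENSG00000286106	0.918699898	0.033431328	Notch2NLR	UP
ENSG00000285253	0.861616516	0.036903938	-	UP
ENSG00000268350	0.773882089	0.018657013	FAM156A	UP
ENSG00000265118	-0.683517083	0.045119276	-	DOWN
ENSG00000178163	-0.597673552	0.045106597	ZNF518B	DOWN
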