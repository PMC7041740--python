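SNP	phenotype_Beta	phenotype_SE	disease_Beta	disease_SE
rs267733	0.0331	0.0053	-0.020408163	0.019802627
rs2710642	0.0239	0.0038	0.015306122	0.009950331
rs10490626	0.0508	0.0069	-0.030612245	0.009950331
rs2030746	0.0214	0.0038	0.015306122	0.009950331
rs1250229	0.0243	0.0042	0.015306122	0.009950331
rs7640978	0.0392	0.0069	-0.030612245	0
rs17404153	0.0336	0.0054	-0.020408163	0
rs4530754	0.0275	0.0036	0.015306122	0.019802627
rs4722551	0.0391	0.0049	0.025510204	0
rs10102164	0.0316	0.0045	0.015306122	0.029558802
rs4942486	0.0243	0.0037	-0.015306122	0.009950331
rs364585	0.0249	0.0038	0.015306122	0.009950331
rs2328223	0.0299	0.005	0.020408163	0.029558802
rs5763662	0.0767	0.0121	0.025510204	0.029558802
rs2479409	0.0642	0.0041	-0.015306122	0.009950331
rs1367117	0.1186	0.004	0.015306122	0.019802627
rs4299376	0.0812	0.0045	-0.015306122	0.009950331
rs3757354	0.0382	0.0044	-0.015306122	0
rs1800562	0.0615	0.008	-0.045918367	0.019802627
rs11220462	0.059	0.0059	0.015306122	0.019802627
rs8017377	0.0303	0.0038	0.020408163	0.019802627
rs7206971	0.0292	0.0055	0.015306122	0.009950331
rs6029526	0.0436	0.0052	0.015306122	0.019802627
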