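del_id	ck_mean_fpkm	npv_mean_fpkm	log2fc	fdr
AY_1247_21697_26716	0.001	0.835	9.705632	0.000158
AY_602_157004_161798	0.355	6.095	4.101735	2.88e-8
AY_20_711178_725997	0.17	2.07	3.606024	1.85e-7
AY_34_1108397_1109641	110.745	934.43	3.076845	2.57e-9
AY_1054_82728_85933	0.43	3.23	2.909126	0.016659
AY_34_288108_295647	0.625	3.52	2.493647	0.005137
AY_1024_125454_134463	1.165	0.575	-1.0187	1.49e-7
AY_874_140748_143694	0.9	0.37	-1.2824	0.001709
AY_261_133645_148170	1	0.38	-1.39593	1.94e-11
AY_545_152779_164768	12.995	4.155	-1.64504	1.65e-17
AY_225_415711_427236	0.305	0.08	-1.93074	8.78e-5
AY_7_943452_945369	0.71	0.001	-9.47168	0.001699
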