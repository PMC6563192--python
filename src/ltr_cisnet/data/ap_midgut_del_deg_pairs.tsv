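del_id	gene_id	gene_name	deg_log2fc
AY_20_711178_725997	evm.TU.AY_20.26	probable E3 ubiquitin-protein ligase sinah	2.269461
AY_225_415711_427236	evm.TU.AY_225.12	facilitated trehalose transporter Tret1-like	-2.0158
AY_225_415711_427236	XLOC_008622	lysine-specific demethylase lid	11.34707
AY_225_415711_427236	evm.TU.AY_225.14	lysine-specific demethylase lid isoform X2	3.464566
AY_225_415711_427236	XLOC_008623		11.94398
AY_261_133645_148170	evm.TU.AY_261.15	glucose dehydrogenase [FAD, quinone]-like	-1.71236
AY_261_133645_148170	evm.TU.AY_261.19	protein singed	1.400687
AY_261_133645_148170	evm.TU.AY_261.18	epsin-2	1.159083
AY_34_288108_295647	evm.TU.AY_34.24	endonuclease and reverse transcriptase-like protein	1.318608
AY_34_1108397_1109641	evm.TU.AY_34.65	protein transport protein Sec61 subunit alpha isoform 2	-1.35623
AY_34_1108397_1109641	evm.TU.AY_34.55	tyrosine-protein kinase CSK isoform X1	2.137612
AY_34_1108397_1109641	evm.TU.AY_34.57	DET1 homolog	1.614551
AY_34_1108397_1109641	evm.TU.AY_34.58	polyubiquitin-B	2.66362
AY_34_1108397_1109641	evm.TU.AY_34.63	midnolin	1.787524
AY_545_152779_164768	XLOC_019487	protein split ends isoform X1	5.019194
AY_545_152779_164768	XLOC_019488		3.989946
AY_545_152779_164768	XLOC_019489	protein split ends isoform X1	4.9572955
AY_545_152779_164768	evm.TU.AY_545.6	ataxin-2-like protein	3.027068
AY_545_152779_164768	evm.TU.AY_545.3	malate dehydrogenase, mitochondrial	-1.42245
AY_545_152779_164768	evm.TU.AY_545.1	nuclear receptor corepressor 1	4.495695
AY_874_140748_143694	evm.TU.AY_874.5	reverse transcriptase	9.748193
AY_874_140748_143694	evm.TU.AY_874.3	zinc finger protein OZF-like	2.395929
AY_874_140748_143694	evm.TU.AY_874.4	zinc finger protein 431-like	2.895531
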