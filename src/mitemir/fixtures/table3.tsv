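mirna	transcript	region	category	p_value	cleavage	mite_production	mite_in_target
miRNA_MITE_3	TraesCS5B02G218100.1	3' UTR	0	0.003	+	MITE_1125	DTT_Hvul_Oleus_AF490468-1
miRNA_MITE_5	TraesCS2A02G281000.1	3' UTR	1	0.008	+	DTT_Tmon_Icarus_BG607724-1	DTT_Hvul_Pan_M801L24-1
miRNA_MITE_5	TraesCS1A02G090300.1	3' UTR	1	0.038	+	DTT_Tmon_Icarus_BG607724-1	DTT_Taes_Icarus_BQ281801-1
miRNA_MITE_7	TraesCS4B02G021400.2	3' UTR	1	0.026	+	DTT_Hvul_Pan_M801L24-1	DTT_Taes_Pan_42j2-6
miRNA_MITE_7	TraesCS2D02G449600.1	3' UTR	0	0.021	+	DTT_Hvul_Pan_M801L24-1	DTT_Taes_Pan_42j2-6
miRNA_MITE_10	TraesCS2D02G578900.1	3' UTR	2	0.021	+	DTT_Bdis_BdisStowawayT_consensus-1	DTT_Bdis_BdisStowawayT_consensus-1
miRNA_MITE_15	TraesCS1B02G479800.1	3' UTR	3	0.043	+	DTT_Taes_Athos_BJ282680-1	DTT_Taes_Athos_BJ282680-1
miRNA_MITE_22	TraesCS7A02G355700.1	3' UTR	1	0.015	+	DTT_Tmon_Icarus_BG607724-1	DTT_Hvul_Pan_M801L24-1
miRNA_MITE_23	TraesCS3A02G333900.1	3' UTR	0	0.007	+	DTT_Tdur_Hades_294D11-1	DTT_Taes_Hades_42j2-4
miRNA_MITE_27	TraesCS2B02G228200.1	3' UTR	0	0.0	+	DTT_Taes_Icarus_BJ263892-1	DTT_Taes_Icarus_BJ306535-1
miRNA_MITE_27	TraesCS6B02G025200.2	3' UTR	0	0.008	+	DTT_Taes_Icarus_BJ263892-1	DTT_Tdur_Icarus_294D11-3
miRNA_MITE_27	TraesCS6B02G069300.2	3' UTR	1	0.006	+	DTT_Taes_Icarus_BJ263892-1	DTT_Tdur_Icarus_294D11-3
miRNA_MITE_27	TraesCS1B02G325200.1	3' UTR	0	0.006	+	DTT_Taes_Icarus_BJ263892-1	DTT_Taes_Icarus_BJ306535-1
miRNA_MITE_27	TraesCS6B02G005300.1	3' UTR	2	0.04	+	DTT_Taes_Icarus_BJ263892-1	DTT_Taes_Icarus_BQ605897-1
miRNA_MITE_27	TraesCS6B02G036100.1	3' UTR	0	0.036	+	DTT_Taes_Icarus_BJ263892-1	DTT_Taes_Icarus_BE517313-1
miRNA_MITE_27	TraesCS2D02G558100.2	3' UTR	1	0.005	+	DTT_Taes_Icarus_BJ263892-1	DTT_Hvul_Icarus_AV928891-1
miRNA_MITE_32	TraesCS3B02G129400.1	3' UTR	1	0.003	+	MITE_1134	MITE_1134
miRNA_MITE_34	TraesCS5B02G444200.1	3' UTR	0	0.002	+	DTT_Tdur_Icarus_103H9-1	MITE_334
miRNA_MITE_34	TraesCS4D02G124600.1	3' UTR	0	0.005	+	DTT_Tdur_Icarus_103H9-1	MITE_394
miRNA_MITE_34	TraesCS1A02G090300.1	3' UTR	1	0.046	+	DTT_Tdur_Icarus_103H9-1	DTT_Taes_Icarus_BQ281801-1
miRNA_MITE_36	TraesCS2A02G281000.3	3' UTR	2	0.027	+	DTT_Taes_Pan_42j2-6	DTT_Hvul_Pan_M801L24-1
miRNA_MITE_36	TraesCS2A02G281000.2	3' UTR	0	0.003	+	DTT_Taes_Pan_42j2-6	DTT_Hvul_Pan_M801L24-1
miRNA_MITE_36	TraesCS7B02G184300.8	3' UTR	0	0.001	+	DTT_Taes_Pan_42j2-6	DTT_Hvul_Pan_M801L24-1
miRNA_MITE_37	TraesCS1D02G273500.1	3' UTR	2	0.031	+	DTT_Tdur_Athos_103H9-1	DTT_Taes_Athos_42j2-5
miRNA_MITE_37	TraesCS3A02G274100.1	3' UTR	0	0.013	+	DTT_Tdur_Athos_103H9-1	DTT_Tdur_Athos_103H9-1
miRNA_MITE_37	TraesCS6B02G168300.1	3' UTR	0	0.007	+	DTT_Tdur_Athos_103H9-1	DTT_Taes_Athos_42j2-4
miRNA_MITE_37	TraesCS6A02G276700.1	3' UTR	2	0.004	+	DTT_Tdur_Athos_103H9-1	DTT_Tmon_Athos_AF326781-1
miRNA_MITE_37	TraesCSU02G068000.1	3' UTR	3	0.009	+	DTT_Tdur_Athos_103H9-1	DTT_Tdur_Athos_103H9-1
miRNA_MITE_37	TraesCS1B02G479800.1	3' UTR	3	0.002	+	DTT_Tdur_Athos_103H9-1	DTT_Taes_Athos_BJ282680-1
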