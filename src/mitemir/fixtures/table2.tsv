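name	locus	strand	sequence	size	mite	annotation	context	genes
MITE_miRNA_1	1A:117385432-117385825	+	UCUGCACCCUGAAUGAUGAAUAGU	24	MITE_524		intergenic
MITE_miRNA_2	1A:169645857-169646029	+	UAGAGAUUUCAAAUGGAACAC	21	DTT_Tdur_Thalos_103H9-1		intron	TraesCS1A02G130800
MITE_miRNA_3	1B:161992200-161992280	+	UCUGUUCACAAAUGUAAGACG	21	MITE_1125	hvu-miR6197	intron	TraesCS1B02G130500
MITE_miRNA_4	1D:147896240-147896319	+	UAUAUUUUGGUACGGAGGGAU	21	MITE_1351		intron	TraesCS1D02G131000
MITE_miRNA_5	2A:133702671-133702770	+	UGAGACGGGUAAUUUGGAACGGAG	24	DTT_Tmon_Icarus_BG607724-1		promoter	TraesCS2A02G175300
MITE_miRNA_6	2A:168984136-168984233	-	UCGGAAUUAGUUGACACUCAAA	22	MITE_926		intron	TraesCS2A02G197900
MITE_miRNA_7	2B:5671327-5671460	-	UAUCUGGACAAAUCUGAGACA	21	DTT_Hvul_Pan_M801L24-1		intron	TraesCS2B02G010300
MITE_miRNA_8	2B:84797244-84797457	-	CAUAAUCUUGAGAAUUGACCCUCC	24	MITE_1243		intergenic
MITE_miRNA_9	2B:482720682-482720772	-	AUCUUCUAUCGUGGGACGAAG	21	DTT_Taes_Athos_BJ320318-1		intron	TraesCS2B02G337800
MITE_miRNA_10	3A:19302861-19302943	+	UCCAAUUACUCGUCGUGGUUU	21	DTT_Bdis_BdisStowawayT_consensus-1	tae-miR5175-5p	intron	TraesCS3A02G033400
MITE_miRNA_11	3B:253488744-253488823	-	AUAUUAUGUGACAGAAGGAGU	21	DTT_Taes_Athos_BJ275764-1		intron	TraesCS3B02G213700
MITE_miRNA_12	3B:587564305-587564383	+	AUUGUGUACAGAGGGAGUAGU	21	MITE_33		intron	TraesCS3B02G374400
MITE_miRNA_13	3D:76935517-76935620	-	AUCCAUAUUAGUUGUCGCUGA	21	DTT_Tmon_Icarus_BG607724-1	bdi-miR5067	promoter, intron	TraesCS3D02G121000,TraesCS3D02G120900
MITE_miRNA_14	3D:472405006-472405092	-	ACACUUAUUUCCGAUCGGAGGG	22	MITE_361		intron	TraesCS3D02G358900
MITE_miRNA_15	3D:508204974-508205052	+	AACUGCUCCCUCCGUAAACUA	21	DTT_Taes_Athos_BJ282680-1		intergenic
MITE_miRNA_16	4A:67171695-67171971	-	ACUUCGAGGACCUGGAUGACU	21	MITE_1191		intergenic
MITE_miRNA_17	4B:429353827-429354091	+	UAAACAUCACAAACUUUGGCC	21	MITE_1569		exon, three_prime_UTR	TraesCS4B02G201300
MITE_miRNA_18	4B:559539958-559540201	+	ACGGUCAAACUUGAAUCUCGGGAA	24	MITE_1490		intergenic
MITE_miRNA_19	4D:18693428-18693534	-	AUUUGAGCGUCAAGUAAUUCU	21	DTT_Taes_Icarus_BQ281801-1		intron	TraesCS4D02G040200
MITE_miRNA_20	4D:142764762-142764979	+	UAGGGUGUAGAAUAAGCUAUU	21	MITE_1731		intergenic
MITE_miRNA_21	4D:142764794-142764971	+	UAGCUUAUUCUACAUCCCAGU	21	MITE_1731		intergenic
MITE_miRNA_22	5A:478013119-478013226	-	UCUGUGACAAGUAAUUCGAAACGG	24	DTT_Tmon_Icarus_BG607724-1	tae-miR1135	intron	TraesCS5A02G266500
MITE_miRNA_23	5A:552632192-552632284	-	UGCGGCACUUAUUUUGGGACG	21	DTT_Tdur_Hades_294D11-1	hvu-miR5049c	intergenic
MITE_miRNA_24	5A:609867615-609867781	+	UUGUAGAGCUUUCAUUAUGGA	21	DTT_Atau_Thalos_AF338431-1		intron	TraesCS5A02G424400
MITE_miRNA_25	5B:272441139-272441265	+	AUCUGUAUGUAGUUUGUAGCGGAA	24	DTT_Hvul_Thalos_AF427791-1		intergenic
MITE_miRNA_26	5D:6108105-6108490	-	UUUGGACAUCUGACAAGCUCU	21	MITE_1134		intergenic
MITE_miRNA_27	5D:156814986-156815098	+	CUCCGUCCGGAAAUAUUUGUGGGA	24	DTT_Taes_Icarus_BJ263892-1		intergenic
MITE_miRNA_28	6A:23496429-23496595	-	UUAGAGGUUUCAAUACGGACU	21	DTT_Taes_Thalos_BJ273584-1		intergenic
MITE_miRNA_29	6B:89431495-89431654	+	CACCUAGUGGAAUCUCUAUAAAGA	24	DTT_Hvul_Thalos_BJ486760-1		intergenic
MITE_miRNA_30	6D:273095753-273095831	+	UCGGUAACUAAAUAUGAGACU	21	MITE_1736		intergenic
MITE_miRNA_31	6D:361524524-361524682	-	UUAGAGAUUUCAAUGUGGAUU	21	DTT_Null_Thalos_consensus-1		intron	TraesCS6D02G256100
MITE_miRNA_32	6D:461512362-461512720	-	AGAUGACCAAAUGAGCUGAAACUU	24	MITE_1134		promoter	TraesCS6D02G38090
MITE_miRNA_33	7A:516155427-516155555	-	AUGGACAAAAAGGGGUGUAUCUAG	24	DTT_Taes_Icarus_42j2-9		intergenic
MITE_miRNA_34	7A:668530082-668530159	+	AUGACGAGUAAAUCAGAACGG	21	DTT_Tdur_Icarus_103H9-1		intergenic
MITE_miRNA_35	7A:668530089-668530164	+	CUUCUGAUUUACUCGUCGUGG	21	DTT_Tdur_Icarus_103H9-1		intergenic
MITE_miRNA_36	7B:34679825-34679952	+	UGUCGUAGAUUUGUCUAGAUA	21	DTT_Taes_Pan_42j2-6	hvu-miR6191	intergenic
MITE_miRNA_37	7B:145795106-145795346	-	UCGGUAAACUAAUAUAAGAGC	21	DTT_Tdur_Athos_103H9-1		intergenic
MITE_miRNA_38	7B:223173899-223174050	+	UGGCAAAUCUAGUUGGUGAGC	21	MITE_955		intron	TraesCS7B02G162500
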