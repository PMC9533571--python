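# Two-PCR zygosity screen of 19 T2 plants of a hexaploid camelina line at
# three insertion loci (pcrA = T-DNA anchored PCR, pcrB = T-DNA flanking PCR).
plant_id	locus_id	pcrA	pcrB
plant1	chr15_982591	+	+
plant2	chr15_982591	+	-
plant3	chr15_982591	-	+
plant4	chr15_982591	+	+
plant5	chr15_982591	+	-
plant6	chr15_982591	-	+
plant7	chr15_982591	-	+
plant8	chr15_982591	+	-
plant9	chr15_982591	+	+
plant10	chr15_982591	+	-
plant11	chr15_982591	+	+
plant12	chr15_982591	+	+
plant13	chr15_982591	-	+
plant14	chr15_982591	-	+
plant15	chr15_982591	+	-
plant16	chr15_982591	+	+
plant17	chr15_982591	+	+
plant18	chr15_982591	+	-
plant19	chr15_982591	+	+
plant1	chr18_7461224	+	+
plant2	chr18_7461224	+	-
plant3	chr18_7461224	+	-
plant4	chr18_7461224	+	+
plant5	chr18_7461224	+	+
plant6	chr18_7461224	+	+
plant7	chr18_7461224	+	-
plant8	chr18_7461224	+	+
plant9	chr18_7461224	+	-
plant10	chr18_7461224	+	+
plant11	chr18_7461224	+	-
plant12	chr18_7461224	+	+
plant13	chr18_7461224	+	+
plant14	chr18_7461224	+	+
plant15	chr18_7461224	+	+
plant16	chr18_7461224	+	+
plant17	chr18_7461224	+	-
plant18	chr18_7461224	+	-
plant19	chr18_7461224	+	+
plant1	chr8_24442089	+	+
plant2	chr8_24442089	+	+
plant3	chr8_24442089	+	+
plant4	chr8_24442089	+	+
plant5	chr8_24442089	+	+
plant6	chr8_24442089	+	+
plant7	chr8_24442089	+	+
plant8	chr8_24442089	+	+
plant9	chr8_24442089	+	+
plant10	chr8_24442089	+	+
plant11	chr8_24442089	+	+
plant12	chr8_24442089	+	+
plant13	chr8_24442089	+	+
plant14	chr8_24442089	+	+
plant15	chr8_24442089	+	+
plant16	chr8_24442089	+	+
plant17	chr8_24442089	+	+
plant18	chr8_24442089	+	+
plant19	chr8_24442089	+	+
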