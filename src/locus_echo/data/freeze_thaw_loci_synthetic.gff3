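##gff-version 3
# Gene-order map of the six S. cerevisiae freeze-thaw tolerance loci
# (AQY1, ATH1, CAR1, POG1, PUT1, YCP4) with three flanking genes per side.
# Gene ORDER, chromosome arms and essential flags follow the public
# S. cerevisiae annotation; COORDINATES ARE SYNTHETIC (approximate, for
# distance arithmetic only).
chrIII	locus_echo	centromere	114386	114501	.	.	.	ID=centromere_chrIII
chrIII	locus_echo	gene	115001	115800	.	+	.	ID=YCR001W;Name=YCR001W
chrIII	locus_echo	gene	116201	117200	.	-	.	ID=CDC10;Name=CDC10
chrIII	locus_echo	gene	117601	118200	.	+	.	ID=MRPL32;Name=MRPL32
chrIII	locus_echo	gene	118601	119300	.	-	.	ID=YCP4;Name=YCP4
chrIII	locus_echo	gene	120101	121500	.	-	.	ID=CIT2;Name=CIT2
chrIII	locus_echo	gene	122001	122600	.	-	.	ID=YCR006C;Name=YCR006C
chrIII	locus_echo	gene	123001	123800	.	-	.	ID=YCR007C;Name=YCR007C
chrIX	locus_echo	centromere	355630	355745	.	.	.	ID=centromere_chrIX
chrIX	locus_echo	gene	126001	129500	.	+	.	ID=YIL125W;Name=YIL125W
chrIX	locus_echo	gene	130201	131400	.	+	.	ID=YIL124W;Name=YIL124W
chrIX	locus_echo	gene	131901	133300	.	+	.	ID=SIM1;Name=SIM1
chrIX	locus_echo	gene	134001	135100	.	+	.	ID=POG1;Name=POG1
chrIX	locus_echo	gene	135801	137400	.	+	.	ID=QDR2;Name=QDR2
chrIX	locus_echo	gene	138001	139700	.	+	.	ID=YIL120W;Name=YIL120W
chrIX	locus_echo	gene	140301	141500	.	-	.	ID=YIL119C;Name=YIL119C
chrXII	locus_echo	centromere	150829	150947	.	.	.	ID=centromere_chrXII
chrXII	locus_echo	gene	418001	419200	.	-	.	ID=YLR139C;Name=YLR139C
chrXII	locus_echo	gene	419901	421100	.	+	.	ID=YLR140W;Name=YLR140W
chrXII	locus_echo	gene	421701	423000	.	+	.	ID=RRN5;Name=RRN5;essential=true
chrXII	locus_echo	gene	423601	425000	.	+	.	ID=PUT1;Name=PUT1
chrXII	locus_echo	gene	425801	427800	.	+	.	ID=DPH6;Name=DPH6
chrXII	locus_echo	gene	428401	429600	.	-	.	ID=YLR144C;Name=YLR144C
chrXII	locus_echo	gene	430201	431600	.	+	.	ID=YLR145W;Name=YLR145W
chrXVI	locus_echo	centromere	555958	556073	.	.	.	ID=centromere_chrXVI
chrXVI	locus_echo	gene	330001	331700	.	+	.	ID=YPL114W;Name=YPL114W
chrXVI	locus_echo	gene	332401	333800	.	-	.	ID=YPL113C;Name=YPL113C
chrXVI	locus_echo	gene	334501	335700	.	-	.	ID=PEX25;Name=PEX25
chrXVI	locus_echo	gene	336401	337400	.	-	.	ID=CAR1;Name=CAR1
chrXVI	locus_echo	gene	338101	339500	.	-	.	ID=GDE1;Name=GDE1
chrXVI	locus_echo	gene	340201	341400	.	-	.	ID=YPL109C;Name=YPL109C
chrXVI	locus_echo	gene	342101	343300	.	+	.	ID=YPL108W;Name=YPL108W
chrXVI	locus_echo	gene	610001	611300	.	-	.	ID=YPR023C;Name=YPR023C
chrXVI	locus_echo	gene	612001	614200	.	+	.	ID=YPR024W;Name=YPR024W
chrXVI	locus_echo	gene	614801	616000	.	-	.	ID=CCL1;Name=CCL1;essential=true
chrXVI	locus_echo	gene	616701	620300	.	+	.	ID=ATH1;Name=ATH1
chrXVI	locus_echo	gene	621001	622100	.	+	.	ID=YPR027C;Name=YPR027C
chrXVI	locus_echo	gene	622801	624000	.	+	.	ID=YPR028W;Name=YPR028W
chrXVI	locus_echo	gene	624701	625900	.	-	.	ID=YPR029C;Name=YPR029C
chrXVI	locus_echo	gene	915001	916400	.	+	.	ID=YPR189W;Name=YPR189W
chrXVI	locus_echo	gene	917101	919100	.	-	.	ID=YPR190C;Name=YPR190C
chrXVI	locus_echo	gene	919801	920900	.	+	.	ID=QCR2;Name=QCR2
chrXVI	locus_echo	gene	921601	922500	.	+	.	ID=AQY1;Name=AQY1
chrXVI	locus_echo	gene	923201	924400	.	-	.	ID=HPA1;Name=HPA1
chrXVI	locus_echo	gene	925101	926300	.	+	.	ID=YPR194C;Name=YPR194C
chrXVI	locus_echo	gene	927001	928200	.	+	.	ID=YPR195C;Name=YPR195C
chrXVI	locus_echo	telomeric_repeat	940001	941000	.	.	.	ID=telomeric_repeat_chrXVI
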