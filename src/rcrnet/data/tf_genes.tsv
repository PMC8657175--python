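# Eleven transcription factors targeting MSGs in MCF7, with the public
# knockdown dataset each was profiled in.
symbol	name	dataset
ESR1	Estrogen receptor 1	GSE10061
FOS	Fos Proto-Oncogene AP-1 Transcription Factor Subunit	GSE36586
FOXM1	Forkhead Box M1	GSE55204
GATA3	GATA Binding Protein 3	GSE39623
HIF1A	Hypoxia Inducible Factor 1 Subunit Alpha	GSE3188
NR5A2	Nuclear Receptor Subfamily 5 Group A Member 2	GSE47803
RARA	Retinoic Acid Receptor Alpha	GSE26298
SPDEF	SAM Pointed Domain Containing ETS Transcription Factor	GSE40985
TFAP2C	Transcription Factor AP-2 Gamma	GSE26740
YBX1	Y-Box Binding Protein 1	GSE28433
ZFX	Zinc Finger Protein X-Linked	ENCSR005AHI
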