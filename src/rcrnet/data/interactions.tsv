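# Curated causal interactions among metastasis suppressor genes (MSGs) and
# their transcription factors, in a BEL subset.  Columns: subject and object
# are the curators' index columns; `statement` is the authoritative causal
# assertion and is what the parser consumes.
#
# Two rows carry an index-column/statement mismatch; the statement text wins:
#   - row indexed MAP2K4/CASP8 asserts p(MAPK14) increases p(CASP8)
#     (edge MAPK14 -> CASP8)
#   - row indexed ESR1/GATA3 asserts p(GATA3) increases p(ESR1)
#     (edge GATA3 -> ESR1)
# The MAPK14 -> CASP8 pair is consequently asserted with both signs (the
# increases row above vs. the directlyDecreases row); the packaged loader
# resolves the conflict in favour of the direct (mechanistic) statement.
subject	object	reference	statement
# -- interactions between metastasis suppressors --
CD44	CASP8	B36	p(CD44) decreases act(p(CASP8))
CD82	CD44	B37	p(CD82) decreases p(CD44)
CD82	BRMS1	B38	p(CD82) increases r(BRMS1)
CD82	CDH1	B39	p(CD82) increases r(CDH1)
CDH1	CASP8	B40	p(CDH1) increases act(p(CASP8))
GSN	CDH2	B41	p(GSN) increases r(CDH2)
MAP2K3	MAPK14	B42	act(comp(p(MAP2K6), p(MAP2K3)), ma(kin)) directlyIncreases p(MAPK14)
MAP2K4	MAP2K7	B43	p(MAP2K4) decreases act(p(MAP2K7), ma(kin))
MAP2K4	MAPK14	B42	p(MAP2K4) directlyIncreases act(p(:MAPK14), ma(kin))
MAP2K4	CASP8	B44	p(MAPK14) increases p(CASP8)
MAP2K6	MAPK14	B42	p(MAP2K6) directlyIncreases p(MAPK14)
MAP2K7	CDH2	B45	p(MAP2K7) increases r(CDH2)
MAPK14	CDH1	B46	p(MAPK14) increases p(CDH1)
MAPK14	CASP8	B47	act(p(MAPK14), ma(kin)) directlyDecreases p(CASP8)
MAPK14	SAP1A	B48	act(p(MAPK14), ma(kin)) directlyIncreases p(ets-Domain Protein Elk-4)
MAPK14	RUNX2	B49	p(MAPK14) increases r(RUNX2)
NME1	BRMS1	B50	p(NME1) decreases r(BRMS1)
NME1	AKAP12	B50	p(NME1) increases r(AKAP12)
NME1	PEBP1	B51	r(NME1) increases r(PEBP1)
PEBP1	MAP2K6	B52	p(PEBP1) increases act(p(MAP2K6))
PEBP1	MAP2K3	B52	p(PEBP1) increases act(p(MAP2K3))
PEBP1	MAPK14	B52	p(PEBP1) increases act(p(MAPK14))
PEBP1	CDH1	B53	p(PEBP1) increases r(CDH1)
RUNX2	CDH2	B54	p(RUNX2) decreases r(CDH2)
RUNX2	CDH1	B54	p(RUNX2) increases r(CDH1)
TGFB1	CDH1	B55	p(TGFB1) decreases r(CDH1)
TGFB1	CDH2	B56	p(TGFB1) decreases r(CDH2)
# -- interactions between metastasis suppressors and regulators --
CDH1	YBX1	B57	p(CDH1) decreases p(YBX1)
CDH1	FOXM1	B58	p(CDH1) decreases p(FOXM1)
ESR1	CDH2	B59	p(ESR1) decreases r(CDH2)
ESR1	CDH1	B60	p(ESR1) directlyIncreases r(CDH1)
ESR1	BRMS1	B61	p(HGNC:ESR1) directlyIncreases r(HGNC:BRMS1)
ESR1	MTA3	B62	p(ESR1) increases r(MTA3)
ESR1	RUNX2	B63	p(ESR1) increases r(RUNX2)
FOS	CDH1	B55	p(FOS) decreases r(CDH1)
FOS	RUNX2	B64	p(FOS) decreases r(RUNX2)
FOS	TGFB1	B55	p(FOS) directlyDecreases r(TGFB1)
FOS	CD44	B65	p(FOS) increases r(CD44)
GATA3	CD44	B66	r(GATA3) directlyIncreases r(CD44)
GATA3	CD44	B66	r(GATA3) directlyIncreases r(CD44)
GATA3	CD44	B66	p(GATA3) increases r(CD44)
GATA3	CD44	B66	p(GATA3) increases r(CD44)
HIF1A	CD44	B67	p(HIF1A) increases r(CD44)
MAP2K4	FOS	B68	p(MAP2K4) increases p(FOS)
MAPK14	FOS	B48	act(p(MAPK14), ma(kin)) increases p(FOS)
MAPK14	GATA3	B69	p(MAPK14) increases act(p(GATA3))
MTA3	CDH2	B62	p(MTA3) decreases r(CDH2)
MTA3	CDH1	B62	p(MTA3) increases r(CDH1)
RELA	BRMS1	B70	p(RELA) directlyDecreases r(BRMS1)
RUNX2	HIF1A	B71	p(RUNX2) increases act(p(HIF1A))
RUNX2	SPDEF	B72	p(RUNX2) directlyDecreases r(SPDEF)
SAP1A	FOS	B48	p(ets-Domain Protein Elk-4) directlyIncreases r(FOS)
SATB1	NME1	B73	p(SATB1) directlyDecreases r(NME1)
SATB1	BRMS1	B73	p(SATB1) directlyDecreases r(BRMS1)
SATB1	CD82	B73	p(SATB1) directlyDecreases r(CD82)
SATB1	CDH1	B73	p(SATB1) directlyDecreases r(CDH1)
SNAI1	CDH1	B74	p(SNAI1) directlyDecreases r(CDH1)
SNAI1	PEBP1	B75	p(SNAI1) directlyDecreases r(PEBP1)
SNAI1	CASP8	B76	p(SNAI1) decreases act(p(CASP8))
TFAP2C	CD44	B77	p(TFAP2C) directlyDecreases r(CD44)
YBX1	CD44	B78	p(YBX1) directlyIncreases r(CD44)
# -- interactions between transcription factors --
ESR1	HIF1A	B79	p(ESR1) directlyIncreases r(HIF1A)
ESR1	GATA3	B20	p(GATA3) increases p(ESR1)
FOXM1	GATA3	B80	p(FOXM1) directlyDecreases r(GATA3)
MTA3	SNAI1	B81	p(MTA3) directlyDecreases r(SNAI1)
NR5A2	ESR1	B82	p(NR5A2) directlyIncreases r(ESR1)
RARA	FOS	B83	p(RARA) decreases act(p(FOS))
RELA	SNAI1	B84	p(RELA) directlyIncreases r(SNAI1)
TFAP2C	ESR1	B85	p(TFAP2C) directlyIncreases r(ESR1)
TNFSF10	CASP8	B86	p(TNFSF10) increases p(CASP8)
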