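# Seventeen metastasis suppressor genes (MSGs), by functional category.
# Symbols are shipped as printed in the source curation (ARGHDIB is the
# curators' spelling of the Rho GDI beta gene).
category	symbol	name
Cell-cell adhesion	CD44	Epican
Cell-cell adhesion	CD82	Tetraspanin 27
Cell-cell adhesion	CDH11	Cadherin 11
Cell-cell adhesion	CDH2	Cadherin 2
Cell-cell adhesion	CDH1	Cadherin 1
Cell-cell adhesion	GSN	Gelsolin
Scaffolding	AKAP12	Gravin/a-kinase anchor protein 12
MAPK	MAP2K6	Dual specificity mitogen-activated protein kinase kinase 6
MAPK	MAP2K4	Dual specificity mitogen-activated protein kinase kinase 4
MAPK	MAP2K7	Dual specificity mitogen-activated protein kinase kinase 7
MAPK	MAPK14	Mitogen-activated protein kinase 14
Transcription	NME1	NME/NM23 Nucleoside Diphosphate Kinase 1
Transcription	BRMS1	Breast cancer metastasis-suppressor 1
GTP-binding	ARGHDIB	Rho GDP Dissociation Inhibitor Beta
GTP-binding	DRG1	Developmentally-regulated GTP-binding protein 1
Other	RRM1	Ribonucleotide Reductase Catalytic Subunit M1
Other	PEBP1	Phosphatidylethanolamine-binding protein 1
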