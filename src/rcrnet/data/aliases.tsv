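# Free-text entity names appearing in curated statements, mapped to HGNC-style
# symbols.  Lookup is case-insensitive.
name	symbol
ets-Domain Protein Elk-4	SAP1A
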