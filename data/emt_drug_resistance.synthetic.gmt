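EMT_SYNTHETIC	synthetic illustrative EMT gene list (not a curated resource)	IGFBP2	POSTN	COL1A1	COL3A1	FN1	VIM	SNAI2
DRUG_RESISTANCE_SYNTHETIC	synthetic illustrative drug-resistance gene list (not a curated resource)	NNMT	IGFBP2	ABCB1	ABCG2	MGMT	COL1A1
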