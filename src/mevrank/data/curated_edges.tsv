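source	relation	target	provenance
TNF	activates	TNFRSF1A	curated
TNFRSF1A	activates	TRADD	curated
TRADD	activates	NFKB1	curated
IL1B	activates	IL1R1	curated
IL1R1	activates	MYD88	curated
TLR1	activates	TIRAP	curated
TLR2	activates	TIRAP	curated
TIRAP	activates	MYD88	curated
MYD88	activates	NFKB1	curated
NFKB1	activates	TNF	curated
NFKB1	activates	IL6	curated
NFKB1	activates	IL1B	curated
NFKB1	activates	IL12B	curated
ICAM1	activates	ITGAL	curated
ITGAL	activates	MAPK1	curated
MAPK1	activates	TNF	curated
ICAM1	inhibits	PTEN	curated
PTEN	inhibits	AKT1	curated
AKT1	activates	NFKB1	curated
CCL5	activates	CCR3	curated
CCL5	activates	CCR5	curated
CCR3	activates	PIK3CA	curated
CCR5	activates	PIK3CA	curated
PIK3CA	activates	AKT1	curated
CCR5	activates	STAT3	curated
STAT3	activates	TGFBR2	curated
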