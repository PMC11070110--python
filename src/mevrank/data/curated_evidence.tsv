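gene	mrna_supported	mrna_direction	mab_confirmed
AKT1	false	none	false
ADORA3	true	down	false
CCL5	true	up	false
CCR3	false	none	false
CCR5	false	none	false
CD36	true	down	false
CD9	true	down	false
FFAR4	true	down	false
ICAM1	true	up	true
IL12B	false	none	false
IL1B	true	up	false
IL1R1	false	none	false
IL6	true	up	false
ITGAL	false	none	false
MAPK1	false	none	false
MRC1	true	down	false
MYD88	false	none	false
NFKB1	false	none	false
PIK3CA	false	none	false
PTEN	false	none	false
STAT3	false	none	false
TGFBR2	true	down	false
TIRAP	false	none	false
TLR1	false	none	false
TLR2	false	none	false
TNF	true	up	true
TNFRSF1A	false	none	false
TRADD	false	none	false
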