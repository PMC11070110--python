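gene	pm_localized	is_receptor	mab_confirmed
AKT1	false	false	false
ADORA3	true	true	false
CCL5	false	false	false
CCR3	true	true	false
CCR5	true	true	false
CD36	true	true	false
CD9	true	false	false
FFAR4	true	true	false
ICAM1	true	true	true
IL12B	false	false	false
IL1B	false	false	false
IL1R1	true	true	false
IL6	false	false	false
ITGAL	true	true	false
MAPK1	false	false	false
MRC1	true	true	false
MYD88	false	false	false
NFKB1	false	false	false
PIK3CA	false	false	false
PTEN	false	false	false
STAT3	false	false	false
TGFBR2	true	true	false
TIRAP	false	false	false
TLR1	true	true	false
TLR2	true	true	false
TNF	false	false	true
TNFRSF1A	true	true	false
TRADD	false	false	false
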