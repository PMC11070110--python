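# Candidate plasma-membrane receptors for the curated macrophage fixture
TNFRSF1A
IL1R1
TLR1
TLR2
ICAM1
CCR3
CCR5
TGFBR2
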