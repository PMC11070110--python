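# Terminal phenotype genes: pro up-regulated in M1, anti down-regulated.
pro: [TNF, IL6, IL1B, IL12B]
anti: [TGFBR2, ADORA3, FFAR4]
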