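WT_1	WT
WT_2	WT
WT_3	WT
KO_1	KO
KO_2	KO
KO_3	KO
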