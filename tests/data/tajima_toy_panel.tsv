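#positions	100	200	300	400	500	600	700	800
POP1	hap0	10010100
POP1	hap1	10001001
POP1	hap2	01001010
POP1	hap3	01000010
POP1	hap4	00100000
POP1	hap5	00000101
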