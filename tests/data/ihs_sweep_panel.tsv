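#positions	20000	40000	60000	80000	100000	120000	140000	160000	180000	200000	220000	240000	260000	280000	300000
POP1	hap0	001010010010100
POP1	hap1	001010010010100
POP1	hap2	001010010010100
POP1	hap3	001010010010100
POP1	hap4	001010010010100
POP1	hap5	001010010010100
POP1	hap6	011001000011111
POP1	hap7	110101001110110
POP1	hap8	000110100101100
POP1	hap9	101111000001011
POP1	hap10	110100100010001
POP1	hap11	000111001110011
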