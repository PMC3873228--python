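icd10	icd9cm
K50	555
K51	556
K52	558
E10	250
E11	250
E14	250
D50	280
D51	281
D62	285
I10	401
I15	405
J45	493
C18	153
D12	211
Z99	V46
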