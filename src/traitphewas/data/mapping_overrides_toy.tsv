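icd10	phewas_code
E12	250.2
D63	285.9
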