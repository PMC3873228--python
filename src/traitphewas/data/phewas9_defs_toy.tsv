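icd9cm	phewas_code	label	exclusion_start	exclusion_end
555	555.1	Regional enteritis	K00	K93
556	555.2	Ulcerative colitis	K00	K93
558	555.9	Other noninfective gastroenteritis	K00	K93
250	250.2	Diabetes mellitus	E00	E90
280	280.1	Iron deficiency anemia	D50	D89
281	281.9	Other deficiency anemia	D50	D89
285	285.9	Other anemia	D50	D89
401	401.1	Essential hypertension	I00	I99
405	401.2	Secondary hypertension	I00	I99
493	495.0	Asthma	J00	J99
153	153.2	Colorectal cancer	C00	D48
211	211.3	Benign neoplasm of intestine	C00	D48
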