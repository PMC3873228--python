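chapter_id	label	start	end
I	Certain infectious and parasitic diseases	A00	B99
II	Neoplasms	C00	D48
III	Diseases of the blood and blood-forming organs	D50	D89
IV	Endocrine, nutritional and metabolic diseases	E00	E90
V	Mental and behavioural disorders	F00	F99
VI	Diseases of the nervous system	G00	G99
VII	Diseases of the eye and adnexa	H00	H59
VIII	Diseases of the ear and mastoid process	H60	H95
IX	Diseases of the circulatory system	I00	I99
X	Diseases of the respiratory system	J00	J99
XI	Diseases of the digestive system	K00	K93
XII	Diseases of the skin and subcutaneous tissue	L00	L99
XIII	Diseases of the musculoskeletal system and connective tissue	M00	M99
XIV	Diseases of the genitourinary system	N00	N99
XV	Pregnancy, childbirth and the puerperium	O00	O99
XVI	Certain conditions originating in the perinatal period	P00	P96
XVII	Congenital malformations, deformations and chromosomal abnormalities	Q00	Q99
XVIII	Symptoms, signs and abnormal clinical and laboratory findings	R00	R99
XIX	Injury, poisoning and certain other consequences of external causes	S00	T98
XX	External causes of morbidity and mortality	V01	Y98
XXI	Factors influencing health status and contact with health services	Z00	Z99
XXII	Codes for special purposes	U00	U99
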