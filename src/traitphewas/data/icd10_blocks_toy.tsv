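block_id	block_label	start	end	chapter_id	chapter_start	chapter_end
C00-C14	Malignant neoplasms of lip, oral cavity and pharynx	C00	C14	II	C00	D48
C15-C26	Malignant neoplasms of digestive organs	C15	C26	II	C00	D48
C30-C39	Malignant neoplasms of respiratory and intrathoracic organs	C30	C39	II	C00	D48
C40-C41	Malignant neoplasms of bone and articular cartilage	C40	C41	II	C00	D48
C43-C44	Melanoma and other malignant neoplasms of skin	C43	C44	II	C00	D48
C45-C49	Malignant neoplasms of mesothelial and soft tissue	C45	C49	II	C00	D48
C50-C50	Malignant neoplasm of breast	C50	C50	II	C00	D48
C51-C58	Malignant neoplasms of female genital organs	C51	C58	II	C00	D48
C60-C63	Malignant neoplasms of male genital organs	C60	C63	II	C00	D48
C64-C68	Malignant neoplasms of urinary tract	C64	C68	II	C00	D48
C69-C72	Malignant neoplasms of eye, brain and central nervous system	C69	C72	II	C00	D48
C73-C75	Malignant neoplasms of thyroid and other endocrine glands	C73	C75	II	C00	D48
C76-C80	Malignant neoplasms of ill-defined and unspecified sites	C76	C80	II	C00	D48
C81-C96	Malignant neoplasms of lymphoid, haematopoietic and related tissue	C81	C96	II	C00	D48
C97-C97	Malignant neoplasms of independent multiple sites	C97	C97	II	C00	D48
D00-D09	In situ neoplasms	D00	D09	II	C00	D48
D10-D36	Benign neoplasms	D10	D36	II	C00	D48
D37-D48	Neoplasms of uncertain or unknown behaviour	D37	D48	II	C00	D48
D50-D53	Nutritional anaemias	D50	D53	III	D50	D89
D55-D59	Haemolytic anaemias	D55	D59	III	D50	D89
D60-D64	Aplastic and other anaemias	D60	D64	III	D50	D89
D65-D69	Coagulation defects, purpura and other haemorrhagic conditions	D65	D69	III	D50	D89
D70-D77	Other diseases of blood and blood-forming organs	D70	D77	III	D50	D89
D80-D89	Certain disorders involving the immune mechanism	D80	D89	III	D50	D89
E00-E07	Disorders of thyroid gland	E00	E07	IV	E00	E90
E10-E14	Diabetes mellitus	E10	E14	IV	E00	E90
E15-E16	Other disorders of glucose regulation and pancreatic internal secretion	E15	E16	IV	E00	E90
E20-E35	Disorders of other endocrine glands	E20	E35	IV	E00	E90
E40-E46	Malnutrition	E40	E46	IV	E00	E90
E50-E64	Other nutritional deficiencies	E50	E64	IV	E00	E90
E65-E68	Obesity and other hyperalimentation	E65	E68	IV	E00	E90
E70-E90	Metabolic disorders	E70	E90	IV	E00	E90
I00-I02	Acute rheumatic fever	I00	I02	IX	I00	I99
I05-I09	Chronic rheumatic heart diseases	I05	I09	IX	I00	I99
I10-I15	Hypertensive diseases	I10	I15	IX	I00	I99
I20-I25	Ischaemic heart diseases	I20	I25	IX	I00	I99
I26-I28	Pulmonary heart disease and diseases of pulmonary circulation	I26	I28	IX	I00	I99
I30-I52	Other forms of heart disease	I30	I52	IX	I00	I99
I60-I69	Cerebrovascular diseases	I60	I69	IX	I00	I99
I70-I79	Diseases of arteries, arterioles and capillaries	I70	I79	IX	I00	I99
I80-I89	Diseases of veins, lymphatic vessels and lymph nodes	I80	I89	IX	I00	I99
I95-I99	Other and unspecified disorders of the circulatory system	I95	I99	IX	I00	I99
J00-J06	Acute upper respiratory infections	J00	J06	X	J00	J99
J09-J18	Influenza and pneumonia	J09	J18	X	J00	J99
J20-J22	Other acute lower respiratory infections	J20	J22	X	J00	J99
J30-J39	Other diseases of upper respiratory tract	J30	J39	X	J00	J99
J40-J47	Chronic lower respiratory diseases	J40	J47	X	J00	J99
J60-J70	Lung diseases due to external agents	J60	J70	X	J00	J99
J80-J84	Other respiratory diseases principally affecting the interstitium	J80	J84	X	J00	J99
J85-J86	Suppurative and necrotic conditions of lower respiratory tract	J85	J86	X	J00	J99
J90-J94	Other diseases of pleura	J90	J94	X	J00	J99
J95-J99	Other diseases of the respiratory system	J95	J99	X	J00	J99
K00-K14	Diseases of oral cavity, salivary glands and jaws	K00	K14	XI	K00	K93
K20-K31	Diseases of oesophagus, stomach and duodenum	K20	K31	XI	K00	K93
K35-K38	Diseases of appendix	K35	K38	XI	K00	K93
K40-K46	Hernia	K40	K46	XI	K00	K93
K50-K52	Noninfective enteritis and colitis	K50	K52	XI	K00	K93
K55-K64	Other diseases of intestines	K55	K64	XI	K00	K93
K65-K67	Diseases of peritoneum	K65	K67	XI	K00	K93
K70-K77	Diseases of liver	K70	K77	XI	K00	K93
K80-K87	Disorders of gallbladder, biliary tract and pancreas	K80	K87	XI	K00	K93
K90-K93	Other diseases of the digestive system	K90	K93	XI	K00	K93
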