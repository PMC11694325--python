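pt	hlt	hlgt	soc	is_tumor	site
Gastric cancer	Gastric neoplasms malignant	Gastrointestinal neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	stomach
Gastric adenocarcinoma	Gastric neoplasms malignant	Gastrointestinal neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	stomach
Metastatic gastric cancer	Gastric neoplasms malignant	Gastrointestinal neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	stomach
Gastric cancer stage III	Gastric neoplasms malignant	Gastrointestinal neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	stomach
Gastric neoplasm	Gastric neoplasms unspecified malignancy	Gastrointestinal neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	stomach
Oesophageal cancer metastatic	Oesophageal neoplasms malignant	Gastrointestinal neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	oesophagus
Renal cell carcinoma	Renal neoplasms malignant	Renal and urinary tract neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	kidney
Renal cancer	Renal neoplasms malignant	Renal and urinary tract neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	kidney
Renal neoplasm	Renal neoplasms unspecified malignancy	Renal and urinary tract neoplasms malignant and unspecified	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	kidney
Adenocarcinoma	Neoplasms malignant site unspecified NEC	Neoplasms malignant and unspecified NEC	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	unspecified
Malignant neoplasm	Neoplasms malignant site unspecified NEC	Neoplasms malignant and unspecified NEC	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	unspecified
Precancerous cells present	Precancerous conditions NEC	Precancerous conditions	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	unspecified
Breast cancer	Breast neoplasms malignant	Breast neoplasms malignant and unspecified (incl nipple)	Neoplasms benign, malignant and unspecified (including cysts and polyps)	1	breast
Diarrhoea	Diarrhoea (excl infective)	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	0
Nausea	Nausea and vomiting symptoms	Gastrointestinal signs and symptoms	Gastrointestinal disorders	0
Vomiting	Nausea and vomiting symptoms	Gastrointestinal signs and symptoms	Gastrointestinal disorders	0
Abdominal pain	Gastrointestinal and abdominal pains	Gastrointestinal signs and symptoms	Gastrointestinal disorders	0
Constipation	Gastrointestinal atonic and hypomotility conditions	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	0
Gastrooesophageal reflux disease	Gastric and oesophageal motility disorders	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	0
Gastric ulcer	Gastroduodenal ulcers and perforation	Gastrointestinal ulceration and perforation	Gastrointestinal disorders	0
Dyspepsia	Dyspeptic signs and symptoms	Gastrointestinal signs and symptoms	Gastrointestinal disorders	0
Renal cyst	Nephropathies NEC	Nephropathies	Renal and urinary disorders	0
Renal mass	Urinary tract signs and symptoms NEC	Urinary tract signs and symptoms	Renal and urinary disorders	0
Nephropathy	Nephropathies NEC	Nephropathies	Renal and urinary disorders	0
Tubulointerstitial nephritis	Nephritis NEC	Nephropathies	Renal and urinary disorders	0
Acute kidney injury	Renal failure and impairment	Renal disorders (excl nephropathies)	Renal and urinary disorders	0
Renal impairment	Renal failure and impairment	Renal disorders (excl nephropathies)	Renal and urinary disorders	0
Fatigue	Asthenic conditions	General system disorders NEC	General disorders and administration site conditions	0
Pyrexia	Febrile disorders	Body temperature conditions	General disorders and administration site conditions	0
Oedema peripheral	Oedema NEC	General system disorders NEC	General disorders and administration site conditions	0
Malaise	Feelings and sensations NEC	General system disorders NEC	General disorders and administration site conditions	0
Drug ineffective	Therapeutic and nontherapeutic responses	Therapeutic and nontherapeutic effects (excl toxicity)	General disorders and administration site conditions	0
Headache	Headaches NEC	Headaches	Nervous system disorders	0
Dizziness	Neurological signs and symptoms NEC	Neurological disorders NEC	Nervous system disorders	0
Rash	Rashes, eruptions and exanthems NEC	Epidermal and dermal conditions	Skin and subcutaneous tissue disorders	0
Pruritus	Pruritus NEC	Epidermal and dermal conditions	Skin and subcutaneous tissue disorders	0
Hypomagnesaemia	Magnesium metabolism disorders	Electrolyte and fluid balance conditions	Metabolism and nutrition disorders	0
Decreased appetite	Appetite disorders	Appetite and general nutritional disorders	Metabolism and nutrition disorders	0
Osteoporosis	Bone related disorders NEC	Bone disorders (excl congenital and fractures)	Musculoskeletal and connective tissue disorders	0
Arthralgia	Joint related signs and symptoms	Joint disorders	Musculoskeletal and connective tissue disorders	0
Pneumonia	Lower respiratory tract and lung infections	Infections - pathogen unspecified	Infections and infestations	0
Clostridium difficile infection	Clostridia infections	Bacterial infectious disorders	Infections and infestations	0
Cough	Coughing and associated symptoms	Respiratory disorders NEC	Respiratory, thoracic and mediastinal disorders	0
Dyspnoea	Breathing abnormalities	Respiratory disorders NEC	Respiratory, thoracic and mediastinal disorders	0
Anaemia	Anaemias NEC	Anaemias nonhaemolytic and marrow depression	Blood and lymphatic system disorders	0
Insomnia	Disturbances in initiating and maintaining sleep	Sleep disorders and disturbances	Psychiatric disorders	0
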