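drug	indication	stage	target	actions	direction	evidence
Erythromycin	Respiratory tract infections	Recruiting	CYP3A7	INHIBITOR	GOF	no
Milrinone	Congestive heart failure	Recruiting	PDE3A	INHIBITOR	GOF	yes
Dapsone	Leprosy and dermatitis herpetiformis	Completed	CYP3A7	SUBSTRATE	LOF	yes
Dapsone	Leprosy and dermatitis herpetiformis	Completed	NAT2	SUBSTRATE	LOF	yes
Theophylline	Chronic asthma	NA	CYP1A2	INHIBITOR;SUBSTRATE	GOF	yes
Theophylline	Chronic asthma	NA	CYP1B1	INHIBITOR;SUBSTRATE	GOF	yes
Theophylline	Chronic asthma	NA	CYP2D6	INHIBITOR;SUBSTRATE	GOF	yes
Theophylline	Chronic asthma	NA	PDE3A	INHIBITOR;SUBSTRATE	GOF	yes
Gefitinib	Metastatic nonsmall cell lung cancer	Completed	CYP1A1	ANTAGONIST	GOF	yes
Gefitinib	Metastatic nonsmall cell lung cancer	Completed	EGFR	ANTAGONIST	GOF	yes
Omeprazole	Duodenal ulcers	Completed	ABCC3	INDUCER	LOF	yes
Omeprazole	Duodenal ulcers	Completed	CYP1A1	INDUCER	LOF	yes
Omeprazole	Duodenal ulcers	Completed	CYP1A2	INDUCER	LOF	yes
Levonorgestrel	Enopausal and postmenopausal disorders	Completed	CYP19A1	INHIBITOR	GOF	yes
Levonorgestrel	Enopausal and postmenopausal disorders	Completed	ESR1	INHIBITOR	GOF	yes
Mexiletine	Ventricular fibrillation	Completed	CYP1A2	INHIBITOR	LOF	yes
Rosiglitazone	Type 2 diabetes mellitus	Completed	CYP2A6	INHIBITOR	GOF	yes
Chloramphenicol	Etracycline-resistant vibrios	Recruiting	CYP3A7	INHIBITOR	GOF	yes
Buspirone	Anxiety disorders	Completed	CYP3A7	SUBSTRATE	LOF	no
Zidovudine	Human immunovirus infections	Completed	CYP2A6	SUBSTRATE;INHIBITOR	GOF	yes
Zidovudine	Human immunovirus infections	Completed	TERT	SUBSTRATE;INHIBITOR	GOF	yes
Flutamide	Prostate cancer	Completed	CYP1B1	SUBSTRATE;INHIBITOR	GOF	yes
Cimetidine	Peptic ulcer disease	Completed	SLC22A5	INHIBITOR	GOF	yes
Cimetidine	Peptic ulcer disease	Completed	CYP3A7	INHIBITOR	GOF	yes
Diclofenac	Osteoarthritis and rheumatoid arthritis	Completed	PLA2G2A	INHIBITOR	GOF	yes
Monobenzone	Skin vitiligo	NA	TYR	INHIBITOR	GOF	yes
Trazodone	Depression	Completed	CYP3A7	SUBSTRATE	LOF	yes
Verapamil	Hypertension, angina, and cluster headache	Completed	SLC22A5	INHIBITOR	GOF	yes
Cefixime	Various infections	Completed	SLC22A5	INHIBITOR	GOF	no
Flurbiprofen	Osteoarthritis and ankylosing spondylitis	Completed	UGT1A1	INHIBITOR	GOF	no
Norethisterone	Dysfunctional Uterine Bleeding	Completed	CYP3A7	SUBSTRATE	LOF	yes
Risperidone	Schizophrenic disorders	Completed	CYP3A7	SUBSTRATE	LOF	yes
Hydrocortisone	Acute Gouty Arthritis	Completed	CYP3A7	SUBSTRATE	LOF	yes
Estradiol	Vasomotor symptoms	Completed	CYP1B1	AGONIST	LOF	yes
Estradiol	Vasomotor symptoms	Completed	CYP2C8	AGONIST	LOF	yes
Estradiol	Vasomotor symptoms	Completed	CYP3A7	AGONIST	LOF	yes
Estradiol	Vasomotor symptoms	Completed	UGT1A1	AGONIST	LOF	yes
Estradiol	Vasomotor symptoms	Completed	ESR1	AGONIST	LOF	yes
Tacrolimus	Heart Transplant Rejection	Completed	CYP3A7	SUBSTRATE	LOF	yes
Zalcitabine	Human Immunodeficiency Virus	Completed	DCK	SUBSTRATE	GOF	yes
Acetylsalicylic acid	Moderate Pain	Completed	EDNRA	INHIBITOR	GOF	yes
Rifampicin	Tuberculosis	Completed	ABCC3	INDUCER;INHIBITOR	GOF	yes
Rifampicin	Tuberculosis	Completed	CYP2A6	INDUCER;INHIBITOR	GOF	yes
Praziquantel	Schistosoma infection	Completed	CYP3A7	SUBSTRATE	LOF	no
Norfloxacin	Urinary tract infection	Recruiting	SLC22A5	INHIBITOR	GOF	yes
Norfloxacin	Urinary tract infection	Recruiting	CYP3A7	INHIBITOR	GOF	yes
Amiodarone	Recurrent ventricular fibrillation	Completed	CYP2A6	INHIBITOR	GOF	yes
Amiodarone	Recurrent ventricular fibrillation	Completed	CYP3A7	INHIBITOR	GOF	yes
Bupropion	Depression, Bipolar	Completed	CYP2A6	SUBSTRATE	LOF	yes
Mitoxantrone	Progressive relapsing	Completed	CYP1B1	INHIBITOR	GOF	yes
Saquinavir	Human Immunodeficiency Virus	Completed	CYP3A7	SUBSTRATE	LOF	yes
Clomipramine	Obsessive Compulsive Disorder	Completed	GSTP1	INHIBITOR	GOF	yes
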