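# term	canonical	source
platelet aggregation	platelet aggregation	EFO
body mass index	body mass index	SNOMED
systolic blood pressure	systolic blood pressure	MeSH
diastolic blood pressure	diastolic blood pressure	EFO
type 2 diabetes	type 2 diabetes	SNOMED
coronary artery disease	coronary artery disease	MeSH
low density lipoprotein cholesterol	low density lipoprotein cholesterol	EFO
high density lipoprotein cholesterol	high density lipoprotein cholesterol	SNOMED
rheumatoid arthritis	rheumatoid arthritis	MeSH
bipolar disorder	bipolar disorder	EFO
crohn disease	crohn disease	SNOMED
fasting glucose	fasting glucose	MeSH
triglyceride levels	triglyceride levels	EFO
bone mineral density	bone mineral density	SNOMED
smoking behaviors	smoking behaviors	MeSH
platelet count	platelet count	EFO
waist hip ratio	waist hip ratio	SNOMED
macular degeneration	macular degeneration	MeSH
prostate cancer	prostate cancer	EFO
celiac disease	celiac disease	SNOMED
blood pressure	blood pressure	EFO
triglycerides	triglyceride levels	EFO
protein c	protein c	SNOMED
diabetes	type 2 diabetes	MeSH
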