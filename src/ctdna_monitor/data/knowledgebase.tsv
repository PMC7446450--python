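gene	alteration_class	variant_pattern	drug	association	escat_tier	evidence_note	source
ERBB2	amplification		trastuzumab	sensitivity	III-A	HER2 amplification predicts trastuzumab benefit; amplified in 3-11% of HGSOC	erbb2-her2
PTEN	mutation_lof		PI3K/mTOR inhibitor	sensitivity	III-A	PTEN loss activates the mTOR pathway	mtor-pi3k
NF1	mutation_lof		PI3K/mTOR inhibitor	sensitivity	III-B	NF1 loss causes mTOR pathway overactivation	mtor-pi3k
PIK3CA	amplification		PI3K/mTOR inhibitor	sensitivity	III-B	PIK3CA amplification can activate PI3K/mTOR signaling	mtor-pi3k
BRCA2	mutation_lof		PARP inhibitor	sensitivity	I-A	HR deficiency confers PARP inhibitor sensitivity in ovarian cancer	hr-parp
STAG2	mutation_lof		PARP inhibitor	sensitivity	III-B	STAG2 loss potentially confers HR deficiency	hr-parp
RAD51C	germline_deletion		PARP inhibitor	sensitivity	II-A	Germline RAD51C loss confers HR deficiency and PARP inhibitor sensitivity	hr-parp
FANCA	deletion		PARP inhibitor	sensitivity	III-B	FANCA loss potentially confers HR deficiency	hr-parp
CDKN1B	deletion		CDK2/4 inhibitor	sensitivity	III-B	CDKN1B loss deregulates cell-cycle control	cdk
CDKN2B	deletion		CDK4/6 inhibitor	sensitivity	III-B	CDKN2B loss predicts CDK4/6 inhibitor sensitivity	cdk
ERBB4	mutation_any		EGFR inhibitor	sensitivity	III-B	ERBB4 mutation predicted to confer EGFR inhibitor sensitivity	egfr
MAPK1	amplification		EGFR inhibitor	resistance	III-B	MAPK1 amplification associated with resistance to EGFR-targeting therapy	egfr
MAPK1	mutation_any		EGFR inhibitor	resistance	III-B	MAPK pathway mutation associated with resistance to EGFR-targeting therapy	egfr
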