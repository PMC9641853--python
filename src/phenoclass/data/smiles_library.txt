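# Small-molecule SMILES library used by the synthetic-data generator.
# One record per line: name<TAB>canonical_smiles. All entries parse with
# RDKit and have average MW in [100, 600] Da.
aspirin	CC(=O)Oc1ccccc1C(=O)O
ibuprofen	CC(C)Cc1ccc(C(C)C(=O)O)cc1
caffeine	Cn1c(=O)c2c(ncn2C)n(C)c1=O
paracetamol	CC(=O)Nc1ccc(O)cc1
naproxen	COc1ccc2cc(C(C)C(=O)O)ccc2c1
diclofenac	O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl
warfarin	CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
atenolol	CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
propranolol	CC(C)NCC(O)COc1cccc2ccccc12
metoprolol	COCCc1ccc(OCC(O)CNC(C)C)cc1
lidocaine	CCN(CC)CC(=O)Nc1c(C)cccc1C
procaine	CCN(CC)CCOC(=O)c1ccc(N)cc1
benzocaine	CCOC(=O)c1ccc(N)cc1
nicotine	CN1CCCC1c1cccnc1
cotinine	CN1C(=O)CCC1c1cccnc1
theophylline	Cn1c(=O)c2[nH]cnc2n(C)c1=O
quinine	C=CC1CN2CCC1CC2C(O)c1ccnc2ccc(OC)cc12
morphine	CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5
codeine	COc1ccc2c3c1OC1C(O)C=CC4C(C2)N(C)CCC341
tramadol	COc1cccc(C2(O)CCCCC2CN(C)C)c1
ketamine	CNC1(c2ccccc2Cl)CCCCC1=O
fluoxetine	CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1
sertraline	CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21
citalopram	CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21
venlafaxine	COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1
bupropion	CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1
diazepam	CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21
alprazolam	Cc1nnc2n1-c1ccc(Cl)cc1C(c1ccccc1)=NC2
zolpidem	Cc1ccc(-c2nc3ccc(C)cn3c2CC(=O)N(C)C)cc1
haloperidol	O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1
risperidone	Cc1nc2n(c(=O)c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2
olanzapine	Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1
quetiapine	OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1
carbamazepine	NC(=O)N1c2ccccc2C=Cc2ccccc21
phenytoin	O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1
valproate	CCCC(CCC)C(=O)O
lamotrigine	Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1
gabapentin	NCC1(CC(=O)O)CCCCC1
pregabalin	CC(C)CC(CN)CC(=O)O
topiramate	CC1(C)OC2COC3(COS(N)(=O)=O)OC(C)(C)OC3C2O1
metformin	CN(C)C(=N)NC(=N)N
glipizide	Cc1cnc(C(=O)NCCc2ccc(S(=O)(=O)NC(=O)NC3CCCCC3)cc2)cn1
pioglitazone	CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1
atorvastatin	CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O
simvastatin	CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21
lovastatin	CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21
fenofibrate	CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1
gemfibrozil	Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1
losartan	CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1
valsartan	CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(=O)O)C(C)C
irbesartan	CCCCC1=NC2(CCCC2)C(=O)N1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1
amlodipine	CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl
nifedipine	COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]
verapamil	COc1ccc(CCN(C)CCCC(C#N)(c2ccc(OC)c(OC)c2)C(C)C)cc1OC
diltiazem	COc1ccc(C2Sc3ccccc3N(CCN(C)C)C(=O)C2OC(C)=O)cc1
captopril	CC(CS)C(=O)N1CCCC1C(=O)O
enalapril	CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O
lisinopril	NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O
hydrochlorothiazide	NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O
furosemide	NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
spironolactone	CC(=O)SC1CCC2(C)C(CCC3(C)C2CCC32CCC(=O)O2)C1
digoxigenin	CC12CCC(O)CC1CCC1C2CC(O)C2(C)C(C3=CC(=O)OC3)CCC12O
prednisone	CC12C=CC(=O)C=C1CCC1C2C(=O)CC2(C)C1CCC2(O)C(=O)CO
dexamethasone	CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO
hydrocortisone	CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO
testosterone	CC12CCC(=O)C=C1CCC1C2CCC2(C)C(O)CCC12
estradiol	CC12CCC3c4ccc(O)cc4CCC3C1CCC2O
progesterone	CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C
tamoxifen	CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1
raloxifene	O=C(c1ccc(OCCN2CCCCC2)cc1)c1c(-c2ccc(O)cc2)sc2ccc(O)cc12
bicalutamide	CC(O)(CS(=O)(=O)c1ccc(F)cc1)C(=O)Nc1ccc(C#N)c(C(F)(F)F)c1
flutamide	CC(C)C(=O)Nc1ccc([N+](=O)[O-])cc1C(F)(F)F
nilutamide	CC1(C)NC(=O)N(c2ccc([N+](=O)[O-])c(C(F)(F)F)c2)C1=O
enzalutamide	CNC(=O)c1ccc(N2C(=O)C(C)(C)N(c3ccc(C#N)c(C(F)(F)F)c3)C2=S)cc1F
abiraterone	Cc1cnccc1C1(C)CCC2C1CCC1CC(O)CCC12C
doxorubicinone	COc1cccc2c1C(=O)c1c(O)c3c(c(O)c1C2=O)CC(O)(C(=O)CO)CC3O
methotrexate	CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1
5-fluorouracil	O=c1[nH]cc(F)c(=O)[nH]1
gemcitabine	Nc1ccn(C2OC(CO)C(O)C2(F)F)c(=O)n1
imatinib	Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1
gefitinib	COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1
erlotinib	C#Cc1cccc(Nc2ncnc3cc(OCCOC)c(OCCOC)cc23)c1
sorafenib	CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1
sunitinib	CCN(CC)CCNC(=O)c1c(C)[nH]c(C=C2C(=O)Nc3ccc(F)cc32)c1C
vorinostat	O=C(CCCCCCC(=O)Nc1ccccc1)NO
celecoxib	Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1
rofecoxib	CS(=O)(=O)c1ccc(C2=C(c3ccccc3)C(=O)OC2)cc1
meloxicam	Cc1cnc(NC(=O)C2=C(O)c3ccccc3S(=O)(=O)N2C)s1
piroxicam	CN1C(C(=O)Nc2ccccn2)=C(O)c2ccccc2S1(=O)=O
indomethacin	COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
sulindac	CC1=C(CC(=O)O)c2cc(F)ccc2C1=Cc1ccc(S(C)=O)cc1
ketoprofen	CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1
omeprazole	COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1
lansoprazole	Cc1c(OCC(F)(F)F)ccnc1CS(=O)c1nc2ccccc2[nH]1
ranitidine	CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1
cimetidine	CN=C(NC#N)NCCSCc1nc[nH]c1C
loratadine	CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1
cetirizine	O=C(O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1
fexofenadine	CC(C)(C(=O)O)c1ccc(C(O)CCCN2CCC(C(O)(c3ccccc3)c3ccccc3)CC2)cc1
diphenhydramine	CN(C)CCOC(c1ccccc1)c1ccccc1
chlorpheniramine	CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1
montelukast	CC(C)(O)c1ccccc1CCC(SCC1(CC(=O)O)CC1)c1cccc(C=Cc2ccc3ccc(Cl)cc3n2)c1
salbutamol	CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
salmeterol	OCc1cc(C(O)CNCCCCCCOCCCCc2ccccc2)ccc1O
theobromine	Cn1cnc2c1c(=O)[nH]c(=O)n2C
trimethoprim	COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC
sulfamethoxazole	Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1
ciprofloxacin	O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O
norfloxacin	CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21
levofloxacin	CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23
metronidazole	Cc1ncc([N+](=O)[O-])n1CCO
fluconazole	OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F
ketoconazole	CC(=O)N1CCN(c2ccc(OCC3COC(Cn4ccnc4)(c4ccc(Cl)cc4Cl)O3)cc2)CC1
itraconazole-frag	CCC(C)n1ncn(-c2ccc(N3CCN(c4ccc(OC)cc4)CC3)cc2)c1=O
chloroquine	CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12
mefloquine	OC(c1cc(C(F)(F)F)nc2c(C(F)(F)F)cccc12)C1CCCCN1
artemisinin	CC1CCC2C(C)C(=O)OC3OC4(C)CCC1C32OO4
mycophenolate	COc1c(C)c2c(c(O)c1CC=C(C)CCC(=O)O)C(=O)OC2
colchicine	COc1cc2c(c(OC)c1OC)-c1ccc(OC)c(=O)cc1C(NC(C)=O)CC2
resveratrol	Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1
curcumin	COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O
quercetin	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12
genistein	O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12
apigenin	O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12
menthol	CC1CCC(C(C)C)C(O)C1
camphor	CC12CCC(CC1=O)C2(C)C
limonene-oxide	C=CC(C)CCC1OC1(C)C
vanillin	COc1cc(C=O)ccc1O
coumarin	O=c1ccc2ccccc2o1
melatonin	COc1ccc2[nH]cc(CCNC(C)=O)c2c1
serotonin	NCCc1c[nH]c2ccc(O)cc12
dopamine	NCCc1ccc(O)c(O)c1
epinephrine	CNCC(O)c1ccc(O)c(O)c1
tryptophan	NC(Cc1c[nH]c2ccccc12)C(=O)O
phenylalanine	NC(Cc1ccccc1)C(=O)O
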