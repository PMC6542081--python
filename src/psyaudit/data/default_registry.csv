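name,atc,long_acting_benzo,anticholinergic
amitriptyline,N06AA09,0,1
clomipramine,N06AA04,0,1
doxepin,N06AA12,0,0
nortriptyline,N06AA10,0,1
citalopram,N06AB04,0,0
escitalopram,N06AB10,0,0
paroxetine,N06AB05,0,0
sertraline,N06AB06,0,0
moclobemide,N06AG02,0,0
mianserin,N06AX03,0,0
mirtazapine,N06AX11,0,0
bupropion,N06AX12,0,0
venlafaxine,N06AX16,0,0
chlorpromazine,N05AA01,0,1
levomepromazine,N05AA02,0,1
fluphenazine,N05AB02,0,0
perphenazine,N05AB03,0,0
prochlorperazine,N05AB04,0,1
haloperidol,N05AD01,0,0
melperone,N05AD03,0,0
sertindole,N05AE03,0,0
flupentixol,N05AF01,0,0
chlorprothixene,N05AF03,0,1
zuclopenthixol,N05AF05,0,0
clozapine,N05AH02,0,0
olanzapine,N05AH03,0,0
quetiapine,N05AH04,0,0
lithium,N05AN01,0,0
risperidone,N05AX08,0,0
diazepam,N05BA01,1,0
oxazepam,N05BA04,0,0
hydroxyzine,N05BB01,0,1
buspirone,N05BE01,0,0
nitrazepam,N05CD02,1,0
flunitrazepam,N05CD03,1,0
midazolam,N05CD08,0,0
zopiclone,N05CF01,0,0
zolpidem,N05CF02,0,0
clomethiazole,N05CM02,0,0
melatonin,N05CH01,0,0
phenobarbital,N03AA02,0,0
phenytoin,N03AB02,0,0
clonazepam,N03AE01,0,0
carbamazepine,N03AF01,0,0
valproic acid,N03AG01,0,0
lamotrigine,N03AX09,0,0
gabapentin,N03AX12,0,0
levetiracetam,N03AX14,0,0
pregabalin,N03AX16,0,0
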