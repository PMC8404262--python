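drug_name,atc_code,class_label,is_anti_infective,alias_of
minocycline,J01AA,Tetracyclines,1,
doxycycline,J01AA,Tetracyclines,1,
ampicillin,J01CA,Penicillins with extended spectrum,1,
amoxicillin,J01CA,Penicillins with extended spectrum,1,
benzylpenicillin,J01CE,Beta-lactamase sensitive penicillins,1,
tazobactam/piperacillin,J01CR,"Combinations of penicillins, incl. beta-lactamase inhibitors",1,
piperacillin-tazobactam,J01CR,"Combinations of penicillins, incl. beta-lactamase inhibitors",1,tazobactam/piperacillin
cefazolin,J01DB,First-generation cephalosporins,1,
cefmetazole,J01DC,Second-generation cephalosporins,1,
cefotiam,J01DC,Second-generation cephalosporins,1,
ceftriaxone,J01DD,Third-generation cephalosporins,1,
ceftazidime,J01DD,Third-generation cephalosporins,1,
cefcapene pivoxil,J01DD,Third-generation cephalosporins,1,
cefepime,J01DE,Fourth-generation cephalosporins,1,
aztreonam,J01DF,Monobactams,1,
meropenem,J01DH,Carbapenems,1,
doripenem,J01DH,Carbapenems,1,
faropenem,J01DI,Other cephalosporins and penems,1,
sulfamethoxazole-trimethoprim,J01EE,"Combinations of sulfonamides and trimethoprim, incl. derivatives",1,
trimethoprim-sulfamethoxazole,J01EE,"Combinations of sulfonamides and trimethoprim, incl. derivatives",1,sulfamethoxazole-trimethoprim
clarithromycin,J01FA,Macrolides,1,
azithromycin,J01FA,Macrolides,1,
clindamycin,J01FF,Lincosamides,1,
streptomycin,J01GA,Streptomycins,1,
amikacin,J01GB,Other aminoglycosides,1,
gentamicin,J01GB,Other aminoglycosides,1,
arbekacin,J01GB,Other aminoglycosides,1,
levofloxacin,J01MA,Fluoroquinolones,1,
ciprofloxacin,J01MA,Fluoroquinolones,1,
garenoxacin,J01MB,Other quinolones,1,
vancomycin,J01XA,Glycopeptide antibacterials,1,
teicoplanin,J01XA,Glycopeptide antibacterials,1,
colistin,J01XB,Polymyxins,1,
fosfomycin,J01XX,Other antibacterials,1,
linezolid,J01XX,Other antibacterials,1,
daptomycin,J01XX,Other antibacterials,1,
amphotericin b,J02AA,Antibiotics,1,
amphotericin,J02AA,Antibiotics,1,amphotericin b
fluconazole,J02AC,Triazole derivatives,1,
itraconazole,J02AC,Triazole derivatives,1,
voriconazole,J02AC,Triazole derivatives,1,
micafungin,J02AX,Other antimycotics for systemic use,1,
caspofungin,J02AX,Other antimycotics for systemic use,1,
acetaminophen,N02BE,Anilides,0,
paracetamol,N02BE,Anilides,0,acetaminophen
loxoprofen,M01AE,Propionic acid derivatives,0,
furosemide,C03CA,Sulfonamide diuretics,0,
omeprazole,A02BC,Proton pump inhibitors,0,
amlodipine,C08CA,Dihydropyridine calcium channel blockers,0,
prednisolone,H02AB,Glucocorticoids,0,
warfarin,B01AA,Vitamin K antagonists,0,
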