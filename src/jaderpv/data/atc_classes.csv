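atc_code,class_label,group
J01AA,Tetracyclines,Antibacterials
J01BA,Amphenicols,Antibacterials
J01CA,Penicillins with extended spectrum,Antibacterials
J01CE,Beta-lactamase sensitive penicillins,Antibacterials
J01CF,Beta-lactamase resistant penicillins,Antibacterials
J01CG,Beta-lactamase inhibitors,Antibacterials
J01CR,"Combinations of penicillins, incl. beta-lactamase inhibitors",Antibacterials
J01DB,First-generation cephalosporins,Antibacterials
J01DC,Second-generation cephalosporins,Antibacterials
J01DD,Third-generation cephalosporins,Antibacterials
J01DE,Fourth-generation cephalosporins,Antibacterials
J01DF,Monobactams,Antibacterials
J01DH,Carbapenems,Antibacterials
J01DI,Other cephalosporins and penems,Antibacterials
J01EA,Trimethoprim and derivatives,Antibacterials
J01EC,Intermediate-acting sulfonamides,Antibacterials
J01ED,Long-acting sulfonamides,Antibacterials
J01EE,"Combinations of sulfonamides and trimethoprim, incl. derivatives",Antibacterials
J01FA,Macrolides,Antibacterials
J01FF,Lincosamides,Antibacterials
J01FG,Streptogramins,Antibacterials
J01GA,Streptomycins,Antibacterials
J01GB,Other aminoglycosides,Antibacterials
J01MA,Fluoroquinolones,Antibacterials
J01MB,Other quinolones,Antibacterials
J01RA,Combinations of antibacterials,Antibacterials
J01XA,Glycopeptide antibacterials,Antibacterials
J01XB,Polymyxins,Antibacterials
J01XC,Steroid antibacterials,Antibacterials
J01XD,Imidazole derivatives,Antibacterials
J01XE,Nitrofuran derivatives,Antibacterials
J01XX,Other antibacterials,Antibacterials
J02AA,Antibiotics,Antimycotics
J02AB,Imidazole derivatives,Antimycotics
J02AC,Triazole derivatives,Antimycotics
J02AX,Other antimycotics for systemic use,Antimycotics
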