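table,group,label,total_n,case_n,ror,ci_low,ci_high
atc_class,Antibacterials,J01AA,1763,75,1.05,0.83,1.32
atc_class,Antibacterials,J01BA,49,0,,,
atc_class,Antibacterials,J01CA,3264,121,0.91,0.76,1.09
atc_class,Antibacterials,J01CE,93,6,1.63,0.71,3.72
atc_class,Antibacterials,J01CF,0,0,,,
atc_class,Antibacterials,J01CG,0,0,,,
atc_class,Antibacterials,J01CR,2121,292,3.81,3.36,4.31
atc_class,Antibacterials,J01DB,1484,46,0.75,0.56,1.01
atc_class,Antibacterials,J01DC,1902,101,1.33,1.08,1.62
atc_class,Antibacterials,J01DD,7551,341,1.12,1.002,1.25
atc_class,Antibacterials,J01DE,1318,128,2.55,2.12,3.06
atc_class,Antibacterials,J01DF,21,4,5.56,1.87,16.51
atc_class,Antibacterials,J01DH,3551,313,2.30,2.05,2.59
atc_class,Antibacterials,J01DI,132,9,1.73,0.88,3.40
atc_class,Antibacterials,J01EA,0,0,,,
atc_class,Antibacterials,J01EC,36,7,5.70,2.50,13.01
atc_class,Antibacterials,J01ED,4,0,,,
atc_class,Antibacterials,J01EE,2738,261,2.51,2.20,2.85
atc_class,Antibacterials,J01FA,5283,200,0.93,0.81,1.07
atc_class,Antibacterials,J01FF,757,55,1.85,1.41,2.44
atc_class,Antibacterials,J01FG,2,0,,,
atc_class,Antibacterials,J01GA,153,9,1.48,0.75,2.89
atc_class,Antibacterials,J01GB,932,258,9.13,7.91,10.55
atc_class,Antibacterials,J01MA,8571,494,1.45,1.33,1.59
atc_class,Antibacterials,J01MB,24,3,3.37,1.01,11.31
atc_class,Antibacterials,J01RA,638,11,0.41,0.23,0.75
atc_class,Antibacterials,J01XA,2752,596,6.68,6.10,7.32
atc_class,Antibacterials,J01XB,137,107,84.62,56.43,126.89
atc_class,Antibacterials,J01XC,2,0,,,
atc_class,Antibacterials,J01XD,667,12,0.43,0.24,0.77
atc_class,Antibacterials,J01XE,0,0,,,
atc_class,Antibacterials,J01XX,2119,107,1.26,1.03,1.53
atc_class,Antimycotics,J02AA,1337,299,6.88,6.05,7.83
atc_class,Antimycotics,J02AB,100,1,,,
atc_class,Antimycotics,J02AC,3130,315,2.67,2.37,3.00
atc_class,Antimycotics,J02AX,1148,161,3.87,3.28,4.58
drug,mono,vancomycin,5101,723,4.00,3.69,4.33
drug,mono,sulfamethoxazole-trimethoprim,15548,938,1.54,1.44,1.65
drug,pair,vancomycin + sulfamethoxazole-trimethoprim,702,76,2.87,2.26,3.65
drug,mono,levofloxacin,11764,627,1.34,1.23,1.45
drug,pair,vancomycin + levofloxacin,563,63,2.98,2.29,3.87
drug,mono,clarithromycin,8040,318,0.97,0.87,1.09
drug,pair,vancomycin + clarithromycin,99,11,2.95,1.58,5.53
drug,mono,meropenem,7303,611,2.19,2.01,2.38
drug,pair,vancomycin + meropenem,1678,184,2.92,2.51,3.41
drug,mono,fluconazole,4961,398,2.08,1.87,2.31
drug,pair,vancomycin + fluconazole,430,53,3.32,2.49,4.43
drug,mono,ceftriaxone,4772,296,1.57,1.39,1.77
drug,pair,vancomycin + ceftriaxone,351,44,3.39,2.47,4.65
drug,mono,itraconazole,4354,254,1.47,1.29,1.67
drug,pair,vancomycin + itraconazole,305,41,3.67,2.64,5.10
drug,mono,cefazolin,4266,198,1.15,0.997,1.33
drug,pair,vancomycin + cefazolin,298,21,1.79,1.15,2.79
drug,mono,cefcapene pivoxil,4262,182,1.05,0.91,1.22
drug,pair,vancomycin + cefcapene pivoxil,58,5,2.23,0.89,5.57
drug,mono,minocycline,4066,218,1.34,1.17,1.54
drug,pair,vancomycin + minocycline,350,43,3.31,2.41,4.56
drug,mono,micafungin,4008,437,2.93,2.65,3.24
drug,pair,vancomycin + micafungin,905,125,3.80,3.14,4.59
drug,mono,cefepime,3971,299,1.94,1.72,2.18
drug,pair,vancomycin + cefepime,652,88,3.69,2.95,4.63
drug,mono,tazobactam/piperacillin,3812,483,3.48,3.16,3.83
drug,pair,vancomycin + tazobactam/piperacillin,584,119,6.07,4.96,7.43
stratum,sex,male,260713,11988,1.31,1.27,1.34
stratum,age,<=19,37941,992,0.62,0.58,0.66
stratum,age,20-29,17049,440,0.62,0.56,0.68
stratum,age,30-39,29004,704,0.57,0.53,0.62
stratum,age,40-49,38486,1247,0.78,0.73,0.82
stratum,age,50-59,63734,2266,0.86,0.82,0.89
stratum,age,60-69,113007,4603,1.00,0.97,1.04
stratum,age,70-79,122114,5527,1.16,1.12,1.20
stratum,age,80-89,61022,3606,1.58,1.52,1.64
stratum,age,>=90,8202,602,1.89,1.74,2.06
stratum,anti_infective_count,0 drugs,495039,19472,0.68,0.65,0.71
stratum,anti_infective_count,1 drug,29938,1529,1.29,1.22,1.36
stratum,anti_infective_count,>=2 drugs,9711,726,1.94,1.80,2.09
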