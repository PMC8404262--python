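pt_code,pt_name
10069339,Acute kidney injury
10001580,Albuminuria
10003885,Azotaemia
10005481,Blood creatinine abnormal
10005483,Blood creatinine increased
10005846,Blood urea abnormal
10005851,Blood urea increased
10068447,Creatinine renal clearance abnormal
10011372,Creatinine renal clearance decreased
10018358,Glomerular filtration rate decreased
10062747,Hypercreatininaemia
10049630,Oedema due to renal disease
10053123,Protein urine present
10037032,Proteinuria
10038428,Renal disorder
10038435,Renal failure
10061480,Renal function test abnormal
10062237,Renal impairment
10038537,Renal tubular disorder
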