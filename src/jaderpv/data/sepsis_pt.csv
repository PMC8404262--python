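pt_code,pt_name
10053840,Bacterial sepsis
10057767,Corynebacterium sepsis
10069802,Device related sepsis
10054219,Enterobacter sepsis
10054221,Enterococcal sepsis
10015296,Escherichia sepsis
10053588,Group B streptococcus neonatal sepsis
10058875,Haemophilus sepsis
10054264,Helicobacter sepsis
10054160,Klebsiella sepsis
10063085,Listeria sepsis
10049151,Neutropenic sepsis
10054047,Pneumococcal sepsis
10058877,Pseudomonal sepsis
10040047,Sepsis
10040049,Sepsis neonatal
10040067,Septic embolus
10040070,Septic shock
10056430,Staphylococcal sepsis
10054137,Stenotrophomonas sepsis
10048960,Streptococcal sepsis
10048709,Urosepsis
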