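atc_code,route,n,median,q1,q3,alpha,alpha_lo,alpha_hi,beta,beta_lo,beta_hi
Total,po,756,5.0,2.0,11.0,10.60,9.68,11.59,0.87,0.82,0.92
Total,iv,1800,5.0,2.0,9.0,8.28,7.88,8.71,1.03,0.99,1.06
J01CR,po,9,3.0,2.5,11.5,8.00,1.94,30.36,0.65,0.34,1.06
J01CR,iv,180,4.0,2.0,8.0,7.43,6.34,8.69,1.04,0.93,1.15
J01DC,po,8,4.5,1.5,9.0,6.95,3.85,12.12,1.79,0.83,3.20
J01DC,iv,56,3.0,1.0,5.8,5.16,3.86,6.82,1.06,0.85,1.30
J01DD,po,93,3.0,1.0,7.0,7.06,5.47,9.06,0.90,0.77,1.05
J01DD,iv,138,4.0,2.0,7.0,7.23,6.01,8.66,1.02,0.89,1.15
J01DE,iv,83,5.0,2.0,11.0,8.24,6.73,10.02,1.19,0.999,1.40
J01DH,iv,190,5.0,2.0,9.0,8.63,7.37,10.08,1.03,0.92,1.14
J01EE,po,112,8.5,4.0,21.0,17.57,13.98,21.94,0.89,0.77,1.01
J01EE,iv,14,3.0,1.8,4.0,3.65,2.54,5.15,1.75,1.12,2.48
J01GB,iv,143,7.0,3.0,11.0,9.64,8.35,11.09,1.27,1.12,1.43
J01MA,po,232,4.0,2.0,8.0,7.62,6.52,8.89,0.92,0.83,1.01
J01MA,iv,95,4.0,2.0,7.0,7.00,5.72,8.53,1.14,0.97,1.33
J01XA,po,10,7.0,2.0,10.3,13.15,4.90,33.47,0.79,0.47,1.18
J01XA,iv,353,5.0,2.0,10.0,8.69,7.82,9.63,1.10,1.01,1.18
J01XB,iv,83,3.0,1.0,6.0,6.25,5.07,7.64,1.26,1.05,1.49
J01XX,po,9,10.0,5.5,12.0,10.06,6.65,14.84,2.07,1.13,3.27
J01XX,iv,39,3.0,1.0,7.0,7.75,4.92,11.98,0.86,0.66,1.09
J02AA,iv,154,5.0,2.0,9.3,9.00,7.45,10.82,0.94,0.83,1.05
J02AC,po,88,9.5,3.0,23.0,19.11,14.82,24.44,0.94,0.79,1.11
J02AC,iv,59,5.0,2.0,18.0,13.06,9.27,18.17,0.83,0.68,1.01
J02AX,iv,82,5.0,3.0,11.0,10.84,8.42,13.86,0.96,0.81,1.12
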