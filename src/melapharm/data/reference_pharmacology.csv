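compound,mt1_pKi,mt1_pKi_sem,mt1_pEC50,mt1_pEC50_sem,mt1_EC50_nM,mt1_Emax,mt1_Emax_sem,mt1_LE,mt2_pKi,mt2_pKi_sem,mt2_pEC50,mt2_pEC50_sem,mt2_EC50_nM,mt2_Emax,mt2_Emax_sem,mt2_LE,selectivity_fold,tanimoto_distance
21,6.31,0.11,7.91,0.05,12.0,93.8,2.5,0.69,6.91,0.05,9.44,0.08,0.36,86.1,3.2,0.83,30.6,0.50
23,5.42,0.03,7.16,0.09,57.5,96.9,5.3,0.56,5.56,0.13,7.69,0.08,20.42,91.7,3.0,0.60,2.7,0.22
28,7.78,0.10,10.39,0.04,0.04,95.3,2.6,0.86,7.63,0.08,10.35,0.10,0.04,69.4,4.0,0.85,0.7,0.05
29,5.22,0.07,6.83,0.06,144.5,87.5,4.5,0.53,5.61,0.05,7.46,0.10,34.67,69.4,8.0,0.58,3.3,0.43
37,5.07,0.13,ND,ND,>30000,ND,ND,ND,5.45,0.10,6.85,0.19,141.25,61.1,9.1,0.53,>1000.0,0.57
44,4.19,0.36,3.33,0.36,57544.0,72.8,4.7,0.33,4.95,0.30,6.58,0.13,263.03,88.9,6.3,0.51,267.2,0.59
45,4.54,0.15,5.06,0.12,8709.6,90.6,14.3,0.44,5.26,0.19,6.37,0.13,426.58,75.0,7.4,0.56,16.9,0.59
47,4.58,0.07,5.25,0.16,2344.2,112.4,5.2,0.46,5.91,0.12,7.99,0.10,10.23,91.7,3.0,0.66,186.9,0.60
54,5.03,0.06,6.06,0.07,741.3,82.8,4.3,0.54,5.56,0.10,7.74,0.10,18.20,75.0,3.7,0.68,36.9,0.43
57,4.84,0.03,5.72,0.11,1778.3,87.5,9.1,0.47,5.37,0.04,6.88,0.15,131.83,66.7,8.3,0.57,10.3,0.53
62,4.32,0.11,4.39,0.42,42658.0,54.1,10.0,0.36,5.49,0.33,7.28,0.14,52.48,58.3,4.8,0.60,875.9,0.64
melatonin,9.06,0.14,11.38,0.06,0.004,100.0,5.6,0.93,9.27,0.14,10.30,0.14,0.05,100.0,5.6,0.84,0.1,0.00
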