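mutant,eps_L1_med,eps_L1_lo,eps_L1_hi,eps_L2_med,eps_L2_lo,eps_L2_hi,gamma1_med,gamma1_lo,gamma1_hi,gamma2_med,gamma2_lo,gamma2_hi
WT,6.61,6.51,6.73,6.62,6.51,6.73,5.29,5.20,5.38,5.29,5.20,5.38
Q32A-E147G,7.29,7.02,7.53,7.27,7.02,7.53,2.45,2.38,2.52,2.45,2.38,2.52
R49G,8.62,8.40,8.84,8.62,8.42,8.85,1.66,1.60,1.72,1.65,1.59,1.71
D53H,5.46,5.09,5.80,5.46,5.05,5.79,1.62,1.57,1.66,1.62,1.57,1.67
P105M,7.23,6.70,7.77,7.24,6.59,7.76,0.92,0.86,0.98,0.92,0.86,0.98
Y132A,2.35,2.15,2.55,2.36,2.17,2.55,6.23,5.97,6.54,6.22,5.96,6.55
G143M,6.92,6.67,7.18,6.91,6.68,7.15,1.52,1.47,1.56,1.52,1.47,1.56
E150Y,6.39,6.01,6.73,6.38,5.99,6.73,1.72,1.66,1.79,1.72,1.66,1.78
PIF,11.05,10.92,11.17,11.05,10.90,11.18,1.54,1.49,1.59,1.54,1.49,1.59
C203V,4.51,4.27,4.74,4.53,4.27,4.78,6.95,5.89,10.23,7.47,6.01,15.84
G102D-T26A,7.23,7.09,7.36,7.22,7.11,7.35,4.31,4.16,4.51,4.31,4.15,4.52
G102D-Y42M-I57N,8.21,8.09,8.34,8.21,8.09,8.34,2.83,2.78,2.89,2.83,2.78,2.88
G102D-K98Q,5.96,5.51,6.36,5.97,5.55,6.37,2.14,2.01,2.28,2.14,2.00,2.29
G102D-L146A,5.70,5.51,5.88,5.70,5.52,5.88,5.43,5.03,6.05,5.42,5.03,6.05
G102D-HQQ,7.56,7.30,7.83,7.57,7.23,7.86,1.54,1.48,1.61,1.54,1.48,1.60
Y132A-G102D-T26A,9.55,8.77,10.25,9.67,8.92,10.51,-2.96,-3.39,-2.58,-3.02,-3.47,-2.66
Y132A-R49G,5.77,5.56,5.98,5.78,5.58,5.98,3.11,3.05,3.16,3.11,3.05,3.16
Y132A-PIF,8.71,8.48,8.93,8.70,8.47,8.93,3.69,3.57,3.84,3.69,3.57,3.83
Y132A-C203V,4.14,3.94,4.32,4.15,3.96,4.34,7.82,6.46,11.12,9.30,6.76,16.72
C203V-R49G,5.40,5.14,5.63,5.39,5.13,5.66,2.38,2.33,2.43,2.38,2.33,2.44
C203V-D53H,5.26,4.98,5.53,5.26,4.97,5.51,1.42,1.39,1.46,1.43,1.39,1.46
C203V-G102D-L146A,3.13,2.81,3.43,3.16,2.78,3.49,6.74,6.00,9.01,6.99,6.03,13.63
C203V-PIF,8.30,7.95,8.61,8.30,7.94,8.65,3.49,3.36,3.64,3.49,3.35,3.64
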