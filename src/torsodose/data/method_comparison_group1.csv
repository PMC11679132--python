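patient,pet_ed,automated_ct,automated_total,physician_ct,physician_total,ct_expo_ct,ct_expo_total,wbcf_0.0082_ct,wbcf_0.0082_total,wbcf_0.015_ct,wbcf_0.015_total
1,6.52,4.46,10.98,4.42,10.94,5.80,12.32,3.08,9.60,5.63,12.15
2,5.76,4.06,9.82,4.01,9.77,5.30,11.06,2.84,8.60,5.19,10.95
3,5.96,4.55,10.51,4.52,10.48,5.90,11.86,3.12,9.08,5.72,11.68
4,5.38,4.12,9.50,4.06,9.44,5.30,10.68,2.81,8.19,5.14,10.52
5,5.14,3.89,9.03,3.85,8.99,5.10,10.24,2.68,7.82,4.91,10.05
6,5.15,4.25,9.40,4.19,9.34,5.60,10.75,2.94,8.09,5.38,10.53
7,4.93,4.50,9.43,4.31,9.24,5.60,10.53,2.99,7.92,5.47,10.40
8,4.69,4.31,9.00,4.25,8.94,5.60,10.29,2.95,7.64,5.39,10.08
9,4.46,3.82,8.28,3.79,8.25,4.90,9.36,2.59,7.05,4.74,9.20
10,4.64,4.25,8.89,4.20,8.84,5.60,10.24,2.96,7.60,5.41,10.05
11,4.57,3.78,8.35,3.74,8.31,4.90,9.47,2.59,7.16,4.73,9.30
12,4.77,4.08,8.85,4.03,8.80,5.40,10.17,2.85,7.62,5.22,9.99
13,4.58,3.92,8.50,3.88,8.46,5.10,9.68,2.69,7.27,4.92,9.50
14,4.68,3.86,8.54,3.82,8.50,5.00,9.68,2.68,7.36,4.90,9.58
15,4.16,3.74,7.90,3.68,7.84,4.80,8.96,2.57,6.73,4.70,8.86
16,4.37,3.85,8.22,3.80,8.17,4.90,9.27,2.62,6.99,4.79,9.16
17,4.23,3.40,7.63,3.34,7.57,4.50,8.73,2.39,6.62,4.37,8.60
18,4.23,3.46,7.69,3.40,7.63,4.50,8.73,2.40,6.63,4.40,8.63
19,3.49,4.01,7.50,3.95,7.44,5.10,8.59,2.73,6.22,4.99,8.48
20,4.11,3.65,7.76,3.62,7.73,4.70,8.81,2.50,6.61,4.58,8.69
21,3.67,3.53,7.20,3.48,7.15,4.60,8.27,2.44,6.11,4.47,8.14
22,4.01,3.76,7.77,3.73,7.74,4.90,8.91,2.59,6.60,4.73,8.74
23,4.23,3.36,7.59,3.31,7.54,4.50,8.73,2.38,6.61,4.35,8.58
24,3.67,3.14,6.81,3.12,6.79,4.10,7.77,2.17,5.84,3.97,7.64
25,3.76,3.00,6.76,2.97,6.73,3.90,7.66,2.08,5.84,3.80,7.56
26,3.63,2.65,6.28,2.62,6.25,3.50,7.13,1.84,5.47,3.37,7.00
27,4.8,2.96,7.76,2.92,7.72,3.80,8.60,2.03,6.83,3.71,8.51
28,3.62,2.92,6.54,2.88,6.50,3.80,7.42,2.00,5.62,3.66,7.28
29,3.62,2.91,6.53,2.87,6.49,3.80,7.42,2.02,5.64,3.70,7.32
30,2.07,1.91,3.98,1.89,3.96,2.90,4.97,1.35,3.42,2.47,4.54
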