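patient,seizure,pattern,duration_s,es_global,es_th,es_mt,es_thmt,so_global,so_th,so_mt,so_thmt,th_out,th_in,mt_out,mt_in
1,1,A,55,0.49,0.51,0.52,0.82,0.19,0.22,0.24,0.51,4.25,0.38,3.13,1.5
1,2,A,90,0.48,0.5,0.53,0.81,0.22,0.25,0.18,0.20,2.17,1.00,3.67,1.00
2,3,A,150,0.46,0.52,0.42,0.47,0.17,0.12,0.17,0.14,3.30,2.20,1.00,3.50
2,4,B,540,0.26,0.21,0.24,0.2,0.15,0.10,0.22,0.14,1.18,0.73,1.55,0.18
3,5,B,59,0.38,0.41,0.34,0.32,0.26,0.22,0.30,0.21,0.50,0.40,1.60,0.60
3,6,B,63,0.33,0.36,0.33,0.42,0.19,0.16,0.24,0.13,0.56,1.22,0.56,0.44
3,7,B,88,0.44,0.45,0.44,0.36,0.22,0.17,0.26,0.18,1.90,1.80,3.00,1.70
4,8,A,60,0.59,0.55,0.59,0.6,0.19,0.12,0.15,0.10,2.91,1.64,2.55,1.82
4,9,A,53,0.49,0.53,0.5,0.53,0.22,0.14,0.19,0.13,0.67,3.17,2.67,0.08
5,10,A,70,0.49,0.58,0.42,0.47,0.14,0.12,0.10,0.13,2.00,1.86,1.29,2.00
5,11,B,126,0.41,0.43,0.4,0.52,0.13,0.14,0.11,0.12,1.75,1.75,2.63,1.25
6,12,B,54,0.36,0.33,0.32,0.29,0.15,0.10,0.12,0.09,0.8,0.70,2.10,0.80
6,13,B,65,0.35,0.37,0.43,0.45,0.17,0.11,0.17,0.12,0.22,1.78,3.33,0.22
7,14,B,200,0.33,0.33,0.38,0.57,0.13,0.12,0.13,0.11,1.50,1.70,2.40,1.00
7,15,B,290,0.29,0.29,0.32,0.4,0.17,0.15,0.16,0.18,0.5,0.50,0.17,1.33
8,16,B,455,0.27,0.27,0.34,0.25,0.11,0.12,0.13,0.29,2.20,0.20,2.20,0.60
8,17,B,70,0.27,0.34,0.39,0.42,0.14,0.18,0.16,0.47,0.25,1.25,1.63,0.38
9,18,B,113,0.31,0.33,0.34,0.55,0.11,0.14,0.10,0.14,1.11,0.78,1.22,0.78
9,19,B,124,0.31,0.42,0.35,0.54,0.16,0.17,0.16,0.19,1.89,0.89,1.22,1.78
10,20,B,64,0.46,0.38,0.42,0.46,0.37,0.28,0.45,0.37,0.60,1.20,1.30,0.80
10,21,B,50,0.37,0.43,0.39,0.38,0.32,0.26,0.42,0.35,0.70,2.50,2.30,0.20
10,22,B,55,0.28,0.38,0.31,0.37,0.22,0.17,0.20,0.12,1.00,1.60,1.70,0.30
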