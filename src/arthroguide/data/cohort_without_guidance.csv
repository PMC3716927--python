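subject,condition,session,avg_cm,sd_cm,time_s
A,without,1,0.288,0.13,24.914
B,without,1,0.7,0.37,13.923
C,without,1,0.204,0.136,28.855
D,without,1,0.476,0.21,13.895
E,without,1,0.331,0.134,15.995
F,without,1,0.541,0.247,14.222
G,without,1,0.378,0.183,16.623
H,without,1,1.525,1.059,30.095
A,without,2,0.183,0.168,13.418
B,without,2,0.45,0.35,13.745
C,without,2,0.447,0.24,14.059
D,without,2,0.383,0.181,9.859
E,without,2,0.212,0.145,15.232
F,without,2,0.261,0.183,7.323
G,without,2,0.219,0.155,15.614
H,without,2,0.545,0.325,12.041
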