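subject,condition,session,avg_cm,sd_cm,time_s
A,with,1,0.168,0.094,13.99
B,with,1,0.109,0.078,11.195
C,with,1,0.575,0.24,15.259
D,with,1,0.248,0.091,9.055
E,with,1,0.1,0.094,19.964
F,with,1,0.374,0.197,9.286
G,with,1,0.378,0.293,9.205
H,with,1,0.135,0.067,9.668
A,with,2,0.107,0.065,11.114
B,with,2,0.482,0.251,13.159
C,with,2,0.357,0.16,8.1
D,with,2,0.234,0.134,9.232
E,with,2,0.173,0.093,13.077
F,with,2,0.187,0.085,8.455
G,with,2,0.116,0.113,11.782
H,with,2,0.126,0.079,8.891
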