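measure,tract,sex,p_exp,p_lin,r_exp,r_lin,t,se_t,rate_exp,rate_lin,T,se_T,sex_sig
fa,CST,M,22,10,0.59,0.59,5.5,1.4,0.005,0.004,18.8,3.3,1
fa,CST,F,27,4,0.53,0.31,2.8,0.6,0.01,0.003,12.4,1.4,1
fa,CG,M,28,19,0.56,0.62,5.3,1.5,0.008,0.004,18.3,3.3,0
fa,CG,F,50,10,0.63,0.52,4.3,0.9,0.01,0.004,15.9,2.1,0
fa,CC,M,19,16,0.61,0.65,5.3,1.3,0.006,0.003,18.2,3.1,0
fa,CC,F,24,8,0.6,0.48,4.4,1.0,0.007,0.003,16.2,2.2,0
fa,IFO,M,23,16,0.52,0.6,6.2,2.0,0.005,0.003,20.3,4.7,0
fa,IFO,F,34,10,0.57,0.42,4.1,0.9,0.008,0.003,15.4,2.1,0
fa,SLF,M,18,22,0.54,0.63,6.8,2.3,0.005,0.003,21.6,5.2,1
fa,SLF,F,38,10,0.54,0.47,3.6,0.8,0.009,0.003,14.2,1.8,1
fa,ILF,M,15,15,0.5,0.56,6.4,2.3,0.004,0.003,20.8,5.2,0
fa,ILF,F,21,13,0.45,0.52,5.8,2.0,0.004,0.003,19.3,4.5,0
fa,UNC,M,20,35,0.5,0.59,7.6,2.9,0.003,0.003,23.4,6.6,0
fa,UNC,F,38,9,0.51,0.29,5.0,1.4,0.006,0.003,17.4,3.2,0
md,ILF,M,61,19,0.52,0.47,5.9,1.9,0.006,0.004,19.6,4.3,1
md,ILF,F,72,3,0.39,0.27,2.7,0.7,0.014,0.004,12.2,1.6,1
md,IFO,M,53,21,0.57,0.57,7.1,2.4,0.005,0.004,22.4,5.5,1
md,IFO,F,64,4,0.48,0.26,3.2,0.8,0.012,0.004,13.3,1.8,1
md,CC,M,35,18,0.55,0.63,6.0,1.9,0.007,0.005,19.8,4.4,0
md,CC,F,36,5,0.44,0.37,4.4,1.3,0.008,0.004,16.0,3.1,0
md,SLF,M,44,41,0.51,0.48,7.6,3.0,0.004,0.004,23.5,6.8,1
md,SLF,F,84,2,0.38,0.20,3.3,1.0,0.009,0.003,13.7,2.4,1
md,UNC,M,60,23,0.58,0.56,6.9,2.2,0.005,0.005,22.1,5.0,0
md,UNC,F,61,15,0.42,0.28,4.3,1.3,0.008,0.005,15.8,3.0,0
md,CG,M,18,19,0.52,0.48,6.7,2.5,0.006,0.006,21.4,5.6,0
md,CG,F,25,1,0.45,0.33,4.7,1.5,0.008,0.004,16.7,3.4,0
md,CST,M,42,22,0.67,0.62,10.3,3.6,0.004,0.004,29.6,8.3,1
md,CST,F,55,2,0.43,0.31,4.2,1.3,0.007,0.003,15.7,2.9,1
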